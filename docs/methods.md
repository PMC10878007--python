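# Methods

## Internal-standard FAME quantification

Quantification assumes already-integrated GC-FID peak areas with
labeled peaks; no peak detection or retention-time alignment is
performed. The mass of fatty acid *i* is

    mass_i = (area_i / area_IS) · m_IS · RRF_i ,

linear in both area and response factor, and invariant to any global
detector gain. Total lipid content is the FAME mass sum over the dry
biomass (default 20 mg per extraction), with the internal standard
excluded.

**Internal-standard mass.** The standard is added as 0.5 mg of
1,2-dinonadecanoyl-sn-glycero-3-phosphocholine (50 µL of a 10 mg/mL
solution). Only its two C19 acyl chains are quantifiable as the C19:0
peak, so the default quantifiable mass is

    m_IS = 0.5 mg · 2·M(C19H38O2)/M(C46H92NO8P)
         = 0.5 · 2·298.50/818.22 = 0.3648 mg ,

computed from atomic weights in `gc_quant.molar_mass`. The conversion
from phospholipid to acyl mass is a modelling choice (the head group
contributes no FAME); `is_mass_mg` is fully overridable in the config
for labs that calibrate differently.

**Mass basis.** Masses are reported on the FAME (methyl ester) basis,
matching the convention of summing FAMEs for lipid content. A
free-acid basis is available via `fame_basis=False`, which rescales by
the C19 ester/acid molar-mass ratio (312.53/298.50).

**Response factors.** No published RRF table is bundled; the default
factor is 1.0 for every analyte, and a two-column TSV (`fa_label`,
`rrf`) can be supplied through `rrf_file`.

## Fatty-acid grammar and classification

The label parser accepts the union of dialects seen in bacterial FAME
reports: prefixes `a-`/`aC…`/`anteiso-`, `i-`/`iso-`, `cyclo-`,
`<pos>OH-`; core `C<carbons>:<double bonds>`; suffixes `n<k>` (omega
position, optionally with `c`/`t`), `cis<k>`/`trans<k>` (delta
position), or bare `c`/`t`. Unparseable labels raise a named error at
parse time but are *kept* during profile summarization under the
unknown class — dropping them would break the closure of class sums to
100 %.

Classification decisions:

* **C6 boundary.** The stated chain-length bounds leave 6 carbons
  unassigned (SCFA < 6; MCFA 7–12). C6 is assigned to MCFA to keep the
  classes contiguous; `c6_class` makes this configurable. Chain classes
  are total and monotone over 2–24 carbons; longer chains are
  `out_of_range`.
* **Precedence.** The reported structural groups are disjoint sums, so
  a total order resolves multi-feature acids: cyclic > hydroxy >
  PUFA > n-MUFA > br-SFA > n-SFA. A branched *and* unsaturated acid
  fits none of the named groups and is counted with the unknowns
  (`br_UFA_unknown`), mirroring how unidentified unsaturated/branched
  peaks are reported in practice.
* **Minor pooling.** Only acids with relative abundance strictly above
  the threshold (default 1 %) are classified; the rest are pooled as
  minor FA per sample on the relative-percent scale. Geometry and
  branching sums run over classified acids only.

## FTIR preprocessing

Grids are stored in descending wavenumber order; intervals are written
(high, low) cm⁻¹. The expected acquisition grid is 4000–400 cm⁻¹ at
1.928 cm⁻¹ digital spacing (1868 points), but any uniform grid works;
a non-uniform grid raises an error instructing resampling rather than
silently filtering on an invalid assumption.

**Savitzky-Golay.** Degree-2 polynomial, window 11 (both configurable),
derivative order 0 (smoothing) or 2. Derivatives are scaled by the grid
spacing, giving absorbance/(cm⁻¹)². Edge points use the standard
interpolating edge mode (polynomial fit to the terminal window), so
output length equals input length. The filter is exact for polynomials
up to the fit degree.

**Region handling.** The multivariate path removes 4000–3100,
2800–1800 and 900–400 cm⁻¹. Removal intervals are closed: a point
exactly on a shared boundary goes with the removed region. This
convention makes the span edges (4000.0 cm⁻¹ is an actual grid point)
behave correctly; no default grid point falls on an interior boundary,
so the choice only matters for constructed grids. `cut_regions` is
idempotent for a fixed interval list.

**EMSC.** Each (second-derivative, cut) spectrum *y* is regressed by
ordinary least squares on {P₀(x), P₁(x), P₂(x), reference}, where x is
the wavenumber affinely mapped to [−1, 1] and P_k are Legendre
polynomials — an orthogonal basis chosen for conditioning; stored
baseline coefficients are in this mapped basis (a₀ is the constant
term; conversion to raw-wavenumber monomials is the standard Legendre
expansion under the affine map). The corrected spectrum is
(y − Σ a_k P_k)/b. By linearity of least squares this removes *any*
degree-≤2 polynomial baseline and positive gain exactly on noiseless
inputs, and re-fitting a corrected spectrum yields b = 1, a = 0. The
reference defaults to the arithmetic mean of the set (EMSC is fitted
over the full dataset, not per replicate); an external reference
spectrum can be supplied. Spectra whose fitted |b| falls below
tolerance (default 10⁻⁶) cannot be meaningfully divided by their gain:
they are flagged in metadata, excluded from PCA with a logged count,
and never silently dropped from ratio tables.

**Ratio path derivative order.** The univariate path defaults to plain
smoothing (derivative order 0) with band heights read from absorbance:
the ratio bands (1742, 1656, 1083 cm⁻¹) are absorbance peaks and
EMSC-corrected spectra are conventionally displayed on the absorbance
scale. A second-derivative variant (`ratio_deriv_order: 2`) is offered,
in which band magnitudes (absolute second-derivative extrema) are used,
since band maxima become minima under the second derivative.

## Band ratios

Band positions for the ester C=O and amide I peaks are reported
variously as 1742/1743/1734 and 1656/1654 cm⁻¹. Defaults are 1742 and
1656; all four band centers are configurable, and the default
extremum-search mode (±8 cm⁻¹ window) makes the result robust to
these 1–9 cm⁻¹ discrepancies. Ratios are invariant to global
multiplicative scaling of a spectrum. Technical replicates are averaged
*after* ratio computation (the ratio of a mean spectrum is not the mean
of ratios); this is configurable by operating on whichever spectrum set
is passed in. A denominator at or below 10⁻¹² flags the spectrum
invalid (NaN ratios) rather than dropping the row.

## PCA and correlation

GC class profiles are autoscaled (sample sd, ddof = 1; zero-variance
columns dropped with a warning) before PCA; FTIR matrices are
mean-centered only — rescaling individual wavenumbers would inflate
noise channels. PCA is a dense SVD of the centered matrix (no
randomized solver; the matrices here are small and bit-reproducibility
is worth more than speed). The input is forced into a fixed memory
layout first because LAPACK results differ in the last bits between
C- and Fortran-ordered inputs. Signs are fixed by making the
largest-magnitude loading of each component positive. Explained
variance fractions are λ_k/Σλ over all singular values.

Grouped Pearson correlations (L/P vs TL%) are computed per group for
the groupings all/Gram/phylum/genus/temperature; groups with fewer than
two pairs or zero variance are reported as undefined with their n, not
omitted. Group mean ± sd tables report sd only for groups with at
least two members; singleton groups carry an absent (empty) sd, never
zero.

## Synthetic panel

The generator emulates the study design the pipeline assumes:
18 genera (6 Gram-negative across Proteobacteria/Bacteroidetes, 12
Gram-positive across Actinobacteria/Firmicutes), by default two strains
per genus, grown at 5/15/25 °C with the seven psychrophilic genera
lacking the 25 °C condition; two biological replicates (GC) and three
technical FTIR replicates per biological sample.

* **Compositions.** Gram-specific templates (Gram-positive dominated by
  a-C15:0/a-C17:0, Gram-negative by C16:1/C18:1n7c/C16:0, each with
  minor hydroxy/cyclic/PUFA/unknown components). Temperature enters as
  a log-abundance slope of ±`effect_size` (default 0.4 per 10 °C) on
  the class the literature reports responding: Gram-negative n-MUFAs up
  at low temperature with n-SFAs compensating, Gram-positive br-SFAs up
  at high temperature with MUFAs/unknowns compensating. True fractions
  are a Dirichlet draw (concentration 400 — a few percent compositional
  noise) around the adjusted template, so they are valid and sum to 1.
* **Lipid content.** True lipid fraction per (strain, temperature) is
  uniform on [0.04, 0.19], the w/w range observed for such panels, so
  recovery tests span the realistic regime.
* **Spectra.** Gaussian bands at 2924, 2853, 1742, 1725, 1709, 1656,
  1640, 1548, 1400, 1240 and 1083 cm⁻¹ (sigmas 7–10 cm⁻¹, consistent
  with 6 cm⁻¹ instrument resolution). Lipid-band amplitudes are
  proportional to the same latent lipid fraction that sets the GC
  truth (amide-relative gain 3.2 per unit fraction); amide bands scale
  with a protein factor (U[0.85, 1.15]); 1083/1240 with a phosphorus
  factor that increases at low temperature. Each spectrum then gets a
  multiplicative gain U[0.7, 1.4], a random degree-2 Legendre baseline
  (coefficient sds 0.02/0.015/0.01 absorbance — modest, as for dried
  films in transmission), and additive Gaussian noise (default sd
  0.005 ≈ 1 % of a large band). Gain and baseline are exactly the
  artifact family EMSC removes; they are pre-drawn into the truth
  ledger so rendering is reproducible.
* **Peak tables** invert the quantification formula (area_i ∝
  mass_i/RRF_i, internal-standard row consistent with m_IS), scaled by
  an arbitrary detector gain, with lognormal multiplicative noise of
  the requested CV on every row.

What the panel does *not* emulate: real FID response variation (RRFs
are 1 in truth and analysis alike), co-elution and misassigned peaks,
Mie-type wavelength-dependent scattering, atmospheric H₂O/CO₂ lines,
detector nonlinearity, amide-band shape changes from protein secondary
structure, and the weak, taxonomy-confounded coupling between FTIR
ratios and GC lipid content seen in real panels. Passing recovery tests
therefore demonstrates the correctness of the computational chain under
its stated model, not field performance on instrument data.

## Problem sizes and determinism

The default end-to-end run (36 strains, 188 GC samples, 564 spectra of
1868 points) completes in a few seconds on one CPU; the test suite and
the acceptance script each finish well under a minute. Every random
draw flows from a single seed (sub-streams are derived per stage,
strain, condition and replicate from it), and repeated runs with the
same seed produce byte-identical output tables.

## Known limitations

* The parser covers the label dialects listed above; exotic notations
  (e.g. multiple double-bond positions like `C18:2n6,9`) raise a parse
  error and the peak is carried as unknown.
* EMSC is the basic polynomial variant; extended Mie-scattering models
  are out of scope.
* Band deconvolution (e.g. amide I secondary-structure fitting) is not
  performed; ratios use single band heights.
* Correlations are descriptive; no significance testing or multiple-
  comparison control is attempted.
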