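"""Seeded synthetic strain panel with known ground truth.

The generator emulates the experimental design this pipeline targets: a
panel of Gram-positive and Gram-negative genera of cold-adapted bacteria
grown at 5/15/25 degC (psychrophilic genera lack the 25 degC condition),
two biological replicates per condition for GC, three technical FTIR
replicates per biological replicate.

Ground-truth structure baked into the panel:

* Gram-specific fatty-acid templates — Gram-positive profiles dominated
  by anteiso-C15:0/anteiso-C17:0, Gram-negative by C16:1/C18:1n7c/C16:0;
* temperature responses — Gram-negative straight-chain MUFA fraction
  rises as temperature falls (with n-SFA compensating), Gram-positive
  branched-SFA fraction rises with temperature; effect sizes are
  log-abundance slopes per 10 degC and are configurable;
* compositional noise via a Dirichlet draw around the temperature-
  adjusted template, keeping fractions valid and summing to one;
* true total lipid fraction of biomass sampled uniformly on
  [0.04, 0.19] (the realistic w/w range for such panels); the same
  latent lipid fraction drives the FTIR lipid-band amplitudes, so the
  L/P-versus-lipid-content correlation has a known positive population
  coupling;
* FTIR spectra as Gaussian bands on the 4000-400 cm-1 grid at
  1.928 cm-1 spacing, plus per-spectrum degree-2 polynomial baseline,
  multiplicative gain and additive noise — exactly the artifact family
  EMSC is designed to remove.

Everything is deterministic given the seed recorded in the truth ledger.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import fa
from .ftir import Spectrum, SpectrumSet
from .gc_quant import DEFAULT_IS_MASS_MG, PeakTable, RRFTable

__all__ = [
    "GenusInfo",
    "StrainMeta",
    "TruthEntry",
    "SyntheticTruth",
    "PanelConfig",
    "GENUS_ROSTER",
    "default_grid",
    "generate_panel",
    "render_peak_table",
    "render_spectrum",
    "render_panel",
    "metadata_frame",
]


@dataclass(frozen=True)
class GenusInfo:
    genus: str
    phylum: str
    gram: str  # "positive" | "negative"
    lifestyle: str  # "psychrophile" | "psychrotroph"


# 18 genera spanning four phyla; psychrophilic genera do not grow at 25 degC.
GENUS_ROSTER: tuple[GenusInfo, ...] = (
    GenusInfo("Polaromonas", "Proteobacteria", "negative", "psychrophile"),
    GenusInfo("Pseudomonas", "Proteobacteria", "negative", "psychrotroph"),
    GenusInfo("Psychrobacter", "Proteobacteria", "negative", "psychrophile"),
    GenusInfo("Shewanella", "Proteobacteria", "negative", "psychrotroph"),
    GenusInfo("Acinetobacter", "Proteobacteria", "negative", "psychrotroph"),
    GenusInfo("Flavobacterium", "Bacteroidetes", "negative", "psychrophile"),
    GenusInfo("Agrococcus", "Actinobacteria", "positive", "psychrotroph"),
    GenusInfo("Arthrobacter", "Actinobacteria", "positive", "psychrotroph"),
    GenusInfo("Brachybacterium", "Actinobacteria", "positive",
              "psychrotroph"),
    GenusInfo("Cryobacterium", "Actinobacteria", "positive", "psychrotroph"),
    GenusInfo("Leifsonia", "Actinobacteria", "positive", "psychrotroph"),
    GenusInfo("Micrococcus", "Actinobacteria", "positive", "psychrotroph"),
    GenusInfo("Paeniglutamicibacter", "Actinobacteria", "positive",
              "psychrophile"),
    GenusInfo("Rhodococcus", "Actinobacteria", "positive", "psychrophile"),
    GenusInfo("Salinibacterium", "Actinobacteria", "positive",
              "psychrophile"),
    GenusInfo("Facklamia", "Firmicutes", "positive", "psychrotroph"),
    GenusInfo("Sporosarcina", "Firmicutes", "positive", "psychrotroph"),
    GenusInfo("Carnobacterium", "Firmicutes", "positive", "psychrophile"),
)

# Template fatty-acid compositions (fractions of total FA weight).
GRAM_NEGATIVE_TEMPLATE: dict[str, float] = {
    "C16:0": 0.22, "C16:1cis9": 0.28, "C18:1n7c": 0.22,
    "C12:0": 0.03, "C17:0": 0.04, "2OH-C14:0": 0.05, "C18:0": 0.04,
    "cyclo-C17:0": 0.03, "C20:5n3": 0.02, "UNK-A": 0.02,
    "C15:0": 0.03, "C10:0": 0.02,
}
GRAM_POSITIVE_TEMPLATE: dict[str, float] = {
    "a-C15:0": 0.32, "a-C17:0": 0.18, "i-C15:0": 0.10, "i-C16:0": 0.05,
    "C16:0": 0.12, "C18:1n9c": 0.06, "C14:0": 0.04, "C22:0": 0.03,
    "UNK-A": 0.06, "C18:2n6c": 0.02, "C16:1cis9": 0.02,
}

# FTIR band roster: center (cm-1) -> Gaussian sigma (cm-1). Widths are on
# the scale expected after 6 cm-1 instrument-resolution smoothing.
BAND_SIGMAS: dict[float, float] = {
    2924.0: 9.0, 2853.0: 8.0, 1742.0: 8.0, 1725.0: 7.0, 1709.0: 7.0,
    1656.0: 10.0, 1640.0: 9.0, 1548.0: 10.0, 1400.0: 9.0, 1240.0: 10.0,
    1083.0: 10.0,
}

GRID_START = 4000.0
GRID_END = 400.0
GRID_SPACING = 1.928


def default_grid() -> np.ndarray:
    """The acquisition grid: 4000 down to 400 cm-1 at 1.928 cm-1."""
    n = int(np.floor((GRID_START - GRID_END) / GRID_SPACING)) + 1
    return GRID_START - GRID_SPACING * np.arange(n)


@dataclass
class PanelConfig:
    """Study-design knobs of the synthetic panel (defaults = the design
    the pipeline assumes)."""

    roster: tuple[GenusInfo, ...] = GENUS_ROSTER
    strains_per_genus: int = 2
    temperatures: tuple[int, ...] = (5, 15, 25)
    bio_replicates: int = 2
    tech_replicates: int = 3
    effect_size: float = 0.4  # log-abundance slope per 10 degC
    dirichlet_concentration: float = 400.0
    lipid_range: tuple[float, float] = (0.04, 0.19)
    lipid_band_gain: float = 3.2  # amide-relative amplitude per lipid frac
    gain_range: tuple[float, float] = (0.7, 1.4)
    baseline_sds: tuple[float, float, float] = (0.02, 0.015, 0.01)
    biomass_dry_mg: float = 20.0

    def __post_init__(self) -> None:
        if self.strains_per_genus < 1 or self.bio_replicates < 1 \
                or self.tech_replicates < 1:
            raise ValueError("replicate/strain counts must be >= 1")
        if not self.roster:
            raise ValueError("empty genus roster")
        if len({g.genus for g in self.roster}) != len(self.roster):
            raise ValueError("duplicate genera in roster")
        lo, hi = self.lipid_range
        if not 0 < lo < hi:
            raise ValueError("invalid lipid_range")


@dataclass(frozen=True)
class StrainMeta:
    strain_id: str
    genus: str
    phylum: str
    gram: str
    lifestyle: str
    temperatures: tuple[int, ...]
    bio_replicates: int = 2
    tech_replicates: int = 3


@dataclass
class TruthEntry:
    """Ground truth for one (strain, temperature) condition."""

    fa_fractions: dict[str, float]
    lipid_fraction: float
    band_amplitudes: dict[float, float]
    protein_factor: float
    phosphorus_factor: float

    @property
    def true_lp_amplitude_ratio(self) -> float:
        return self.band_amplitudes[1742.0] / self.band_amplitudes[1656.0]


@dataclass
class SyntheticTruth:
    """Truth ledger: the seed plus everything the panel was built from."""

    seed: int
    entries: dict[tuple[str, int], TruthEntry] = field(default_factory=dict)
    # (strain, temp, bio, tech) -> (gain, a0, a1, a2) per spectrum
    artifacts: dict[tuple[str, int, int, int],
                    tuple[float, float, float, float]] = \
        field(default_factory=dict)

    def entry(self, strain_id: str, temperature: int) -> TruthEntry:
        return self.entries[(strain_id, temperature)]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "entries": {
                f"{s}|{t}": {
                    "fa_fractions": e.fa_fractions,
                    "lipid_fraction": e.lipid_fraction,
                    "band_amplitudes": {
                        str(c): a for c, a in e.band_amplitudes.items()
                    },
                    "protein_factor": e.protein_factor,
                    "phosphorus_factor": e.phosphorus_factor,
                }
                for (s, t), e in self.entries.items()
            },
            "artifacts": {
                f"{s}|{t}|{b}|{k}": list(v)
                for (s, t, b, k), v in self.artifacts.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        truth = cls(seed=int(payload["seed"]))
        for key, e in payload["entries"].items():
            s, t = key.rsplit("|", 1)
            truth.entries[(s, int(t))] = TruthEntry(
                fa_fractions=dict(e["fa_fractions"]),
                lipid_fraction=float(e["lipid_fraction"]),
                band_amplitudes={
                    float(c): float(a)
                    for c, a in e["band_amplitudes"].items()
                },
                protein_factor=float(e["protein_factor"]),
                phosphorus_factor=float(e["phosphorus_factor"]),
            )
        for key, v in payload["artifacts"].items():
            s, t, b, k = key.rsplit("|", 3)
            truth.artifacts[(s, int(t), int(b), int(k))] = tuple(
                float(x) for x in v
            )
        return truth


def _label_beta(label: str, gram: str, effect: float) -> float:
    """Log-abundance temperature slope for one template fatty acid."""
    try:
        cls = fa.structural_class(fa.parse_fa_label(label))
    except fa.FAParseError:
        cls = "unknown"
    if gram == "negative":
        if cls == "n_MUFA":
            return -effect
        if cls == "n_SFA":
            return +effect
    else:
        if cls == "br_SFA":
            return +effect
        if cls in ("n_MUFA", "unknown"):
            return -effect
    return 0.0


def _template_at(gram: str, temperature: int, effect: float
                 ) -> dict[str, float]:
    base = GRAM_NEGATIVE_TEMPLATE if gram == "negative" \
        else GRAM_POSITIVE_TEMPLATE
    dt = (temperature - 15.0) / 10.0
    weights = {
        label: w * float(np.exp(_label_beta(label, gram, effect) * dt))
        for label, w in base.items()
    }
    total = sum(weights.values())
    return {label: w / total for label, w in weights.items()}


def _band_amplitudes(lipid_fraction: float, protein_factor: float,
                     phosphorus_factor: float, lipid_band_gain: float
                     ) -> dict[float, float]:
    ls = lipid_band_gain * lipid_fraction
    return {
        2924.0: 0.55 * ls,
        2853.0: 0.30 * ls,
        1742.0: 1.00 * ls,
        1725.0: 0.10 * ls,
        1709.0: 0.08 * ls,
        1656.0: 0.65 * protein_factor,
        1640.0: 0.33 * protein_factor,
        1548.0: 0.45 * protein_factor,
        1400.0: 0.12 * protein_factor + 0.08 * phosphorus_factor,
        1240.0: 0.28 * phosphorus_factor,
        1083.0: 0.50 * phosphorus_factor,
    }


def generate_panel(
    config: PanelConfig | None = None, seed: int = 0
) -> tuple[list[StrainMeta], SyntheticTruth]:
    """Generate the strain panel and its truth ledger, deterministically.

    Strains are enumerated in roster order, each grown at every roster
    temperature its lifestyle allows. For each (strain, temperature) the
    true fatty-acid composition is a Dirichlet draw around the Gram- and
    temperature-adjusted template, the true lipid fraction a uniform draw
    on ``config.lipid_range``, and the FTIR band amplitudes follow the
    latent lipid/protein/phosphorus factors. Per-spectrum baseline and
    gain artifacts are pre-drawn into the ledger.
    """
    config = config or PanelConfig()
    rng = np.random.default_rng(seed)
    strains: list[StrainMeta] = []
    truth = SyntheticTruth(seed=seed)

    for info in config.roster:
        temps = tuple(
            t for t in config.temperatures
            if not (info.lifestyle == "psychrophile" and t >= 25)
        )
        for i in range(config.strains_per_genus):
            strain_id = f"{info.genus[:4]}-{i + 1:02d}"
            strains.append(StrainMeta(
                strain_id=strain_id, genus=info.genus, phylum=info.phylum,
                gram=info.gram, lifestyle=info.lifestyle,
                temperatures=temps,
                bio_replicates=config.bio_replicates,
                tech_replicates=config.tech_replicates,
            ))
            for t in temps:
                template = _template_at(info.gram, t, config.effect_size)
                labels = list(template)
                alpha = config.dirichlet_concentration * np.array(
                    [template[label] for label in labels]
                )
                fractions = rng.dirichlet(alpha)
                lipid = float(rng.uniform(*config.lipid_range))
                protein = float(rng.uniform(0.85, 1.15))
                phosphorus = float(
                    rng.uniform(0.6, 1.0)
                    * np.exp(0.15 * (15.0 - t) / 10.0)
                )
                truth.entries[(strain_id, t)] = TruthEntry(
                    fa_fractions=dict(zip(labels, map(float, fractions))),
                    lipid_fraction=lipid,
                    band_amplitudes=_band_amplitudes(
                        lipid, protein, phosphorus, config.lipid_band_gain
                    ),
                    protein_factor=protein,
                    phosphorus_factor=phosphorus,
                )
                for b in range(config.bio_replicates):
                    for k in range(config.tech_replicates):
                        gain = float(rng.uniform(*config.gain_range))
                        a0, a1, a2 = (
                            float(rng.normal(0.0, sd))
                            for sd in config.baseline_sds
                        )
                        truth.artifacts[(strain_id, t, b, k)] = (
                            gain, a0, a1, a2
                        )
    return strains, truth


def _sub_rng(seed: int, tag: int, strain_id: str, temperature: int,
             replicate: int) -> np.random.Generator:
    # Stable stream per (seed, stage, strain, condition, replicate).
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, tag, zlib.crc32(strain_id.encode()),
         temperature, replicate]
    )


def sample_name(strain_id: str, temperature: int, bio: int) -> str:
    return f"{strain_id}_T{temperature:02d}_b{bio + 1}"


def render_peak_table(
    truth: SyntheticTruth,
    strain_id: str,
    temperature: int,
    noise_cv: float = 0.0,
    replicate: int = 0,
    rrf: RRFTable | None = None,
    biomass_dry_mg: float = 20.0,
    is_mass_mg: float = DEFAULT_IS_MASS_MG,
    is_label: str = "C19:0",
) -> PeakTable:
    """Forward-model one GC-FID peak table from the truth ledger.

    True fatty-acid masses are the lipid fraction times the dry biomass,
    split by the true composition; areas invert the internal-standard
    quantification (area_i = mass_i / RRF_i, IS row = is_mass_mg), all
    scaled by an arbitrary per-run detector gain and multiplied by
    lognormal noise with coefficient of variation ``noise_cv``.
    """
    entry = truth.entry(strain_id, temperature)
    rrf = rrf or RRFTable()
    rng = _sub_rng(truth.seed, 17, strain_id, temperature, replicate)
    gain = float(rng.uniform(0.5, 2.0)) * 1e4  # arbitrary detector units

    total_fa_mg = entry.lipid_fraction * biomass_dry_mg
    areas = {
        label: total_fa_mg * frac / rrf.get(label) * gain / is_mass_mg
        for label, frac in entry.fa_fractions.items()
    }
    areas[is_label] = gain
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
        for label in areas:
            areas[label] *= float(
                rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma)
            )
    return PeakTable(
        sample_id=sample_name(strain_id, temperature, replicate),
        areas=areas,
        biomass_dry_mg=biomass_dry_mg,
        is_label=is_label,
        is_mass_mg=is_mass_mg,
    )


def render_spectrum(
    truth: SyntheticTruth,
    strain_id: str,
    temperature: int,
    replicate: tuple[int, int] = (0, 0),
    noise_sd: float = 0.0,
    include_artifacts: bool = True,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Forward-model one FTIR absorbance spectrum.

    The clean spectrum is the Gaussian band sum for the condition's true
    amplitudes; with ``include_artifacts`` the pre-drawn multiplicative
    gain and degree-2 Legendre baseline for this replicate are applied,
    then additive Gaussian noise of ``noise_sd``.
    """
    bio, tech = replicate
    entry = truth.entry(strain_id, temperature)
    w = default_grid() if grid is None else np.asarray(grid, float)
    values = np.zeros_like(w)
    for center, amp in entry.band_amplitudes.items():
        sigma = BAND_SIGMAS[center]
        values += amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)

    if include_artifacts:
        gain, a0, a1, a2 = truth.artifacts[
            (strain_id, temperature, bio, tech)
        ]
        x = 2.0 * (w - w.min()) / (w.max() - w.min()) - 1.0
        baseline = np.polynomial.legendre.legval(x, [a0, a1, a2])
        values = gain * values + baseline
    if noise_sd > 0:
        rng = _sub_rng(truth.seed, 29, strain_id, temperature,
                       bio * 1000 + tech)
        values = values + rng.normal(0.0, noise_sd, size=w.shape)
    return Spectrum(
        wavenumbers=w,
        values=values,
        sample_id=sample_name(strain_id, temperature, bio),
        replicate=tech,
    )


def metadata_frame(strains: list[StrainMeta]) -> pd.DataFrame:
    """Tidy per-biological-sample metadata table."""
    rows = []
    for s in strains:
        for t in s.temperatures:
            for b in range(s.bio_replicates):
                rows.append({
                    "sample_id": sample_name(s.strain_id, t, b),
                    "strain_id": s.strain_id,
                    "genus": s.genus,
                    "phylum": s.phylum,
                    "gram": s.gram,
                    "lifestyle": s.lifestyle,
                    "temperature": t,
                    "bio_replicate": b + 1,
                })
    return pd.DataFrame(rows)


def render_panel(
    strains: list[StrainMeta],
    truth: SyntheticTruth,
    noise_cv: float = 0.05,
    noise_sd: float = 0.005,
    biomass_dry_mg: float = 20.0,
) -> tuple[list[PeakTable], SpectrumSet]:
    """Render every peak table and spectrum of the panel."""
    tables: list[PeakTable] = []
    spectra: list[Spectrum] = []
    for s in strains:
        for t in s.temperatures:
            for b in range(s.bio_replicates):
                tables.append(render_peak_table(
                    truth, s.strain_id, t, noise_cv=noise_cv,
                    replicate=b, biomass_dry_mg=biomass_dry_mg,
                ))
                for k in range(s.tech_replicates):
                    spectra.append(render_spectrum(
                        truth, s.strain_id, t, replicate=(b, k),
                        noise_sd=noise_sd,
                    ))
    return tables, SpectrumSet.from_spectra(spectra)
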