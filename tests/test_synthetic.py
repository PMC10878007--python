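"""Synthetic panel generator: determinism, truth structure, round trips."""

import numpy as np
import pytest

from coldchem import fa, gc_quant
from coldchem.bands import compute_ratios
from coldchem.ftir import SpectrumSet, pipeline_pca
from coldchem.synthetic import (
    BAND_SIGMAS,
    GENUS_ROSTER,
    PanelConfig,
    SyntheticTruth,
    _template_at,
    generate_panel,
    metadata_frame,
    render_peak_table,
    render_spectrum,
)


def test_fixed_seed_reproduces_the_panel(small_panel):
    config, strains, truth = small_panel
    strains2, truth2 = generate_panel(config, seed=7)
    assert strains == strains2
    for key, entry in truth.entries.items():
        other = truth2.entries[key]
        assert entry.fa_fractions == other.fa_fractions
        assert entry.lipid_fraction == other.lipid_fraction
        assert entry.band_amplitudes == other.band_amplitudes
    assert truth.artifacts == truth2.artifacts


def test_compositional_closure(small_panel):
    _, _, truth = small_panel
    for entry in truth.entries.values():
        assert sum(entry.fa_fractions.values()) == \
            pytest.approx(1.0, abs=1e-12)
        assert all(f >= 0 for f in entry.fa_fractions.values())


def test_psychrophiles_lack_the_25C_condition(small_panel):
    _, strains, _ = small_panel
    for s in strains:
        if s.lifestyle == "psychrophile":
            assert 25 not in s.temperatures
        else:
            assert s.temperatures == (5, 15, 25)


def test_lipid_fractions_span_the_configured_range(small_panel):
    config, _, truth = small_panel
    lo, hi = config.lipid_range
    values = [e.lipid_fraction for e in truth.entries.values()]
    assert min(values) >= lo and max(values) <= hi


def test_zero_effect_size_removes_temperature_dependence():
    for gram in ("negative", "positive"):
        t5 = _template_at(gram, 5, 0.0)
        t25 = _template_at(gram, 25, 0.0)
        assert t5 == t25


def test_gram_negative_mufa_increases_at_low_temperature():
    """Monte-Carlo over the generator's own rules at n = 20 strains."""
    config = PanelConfig(
        roster=tuple(g for g in GENUS_ROSTER if g.gram == "negative"),
        strains_per_genus=4,  # 6 genera x 4 > 20 strains
    )
    _, truth = generate_panel(config, seed=11)

    def mean_mufa(temp):
        vals = []
        for (_, t), entry in truth.entries.items():
            if t != temp:
                continue
            mufa = sum(
                frac for label, frac in entry.fa_fractions.items()
                if not label.startswith("UNK")
                and fa.structural_class(fa.parse_fa_label(label))
                == "n_MUFA"
            )
            vals.append(mufa)
        return np.mean(vals)

    assert mean_mufa(5) > mean_mufa(25)


def test_gram_positive_br_sfa_increases_with_temperature():
    config = PanelConfig(
        roster=tuple(g for g in GENUS_ROSTER
                     if g.gram == "positive"
                     and g.lifestyle == "psychrotroph"),
        strains_per_genus=3,
    )
    _, truth = generate_panel(config, seed=13)
    by_temp = {5: [], 25: []}
    for (_, t), entry in truth.entries.items():
        if t in by_temp:
            br = sum(
                frac for label, frac in entry.fa_fractions.items()
                if not label.startswith("UNK")
                and fa.structural_class(fa.parse_fa_label(label))
                == "br_SFA"
            )
            by_temp[t].append(br)
    assert np.mean(by_temp[25]) > np.mean(by_temp[5])


class TestPeakTableRoundTrip:
    def test_zero_noise_recovers_true_masses_exactly(self, small_panel):
        config, strains, truth = small_panel
        s = strains[0]
        t = s.temperatures[0]
        entry = truth.entry(s.strain_id, t)
        pt = render_peak_table(truth, s.strain_id, t, noise_cv=0.0)
        profile = gc_quant.quantify_fames(pt)
        total = entry.lipid_fraction * pt.biomass_dry_mg
        for label, frac in entry.fa_fractions.items():
            assert profile.masses[label] == \
                pytest.approx(total * frac, rel=1e-12)
        tl = gc_quant.total_lipid_content(profile, pt.biomass_dry_mg)
        assert tl == pytest.approx(100.0 * entry.lipid_fraction,
                                   rel=1e-12)

    def test_detector_gain_cancels_downstream(self, small_panel):
        _, strains, truth = small_panel
        s = strains[1]
        t = s.temperatures[0]
        pt = render_peak_table(truth, s.strain_id, t, noise_cv=0.0)
        scaled = gc_quant.PeakTable(
            pt.sample_id, {k: 10.0 * v for k, v in pt.areas.items()},
            pt.biomass_dry_mg, pt.is_label, pt.is_mass_mg,
        )
        tl1 = gc_quant.total_lipid_content(
            gc_quant.quantify_fames(pt), pt.biomass_dry_mg)
        tl2 = gc_quant.total_lipid_content(
            gc_quant.quantify_fames(scaled), pt.biomass_dry_mg)
        assert tl2 == pytest.approx(tl1, rel=1e-14)

    def test_class_sums_match_truth_at_zero_noise(self, small_panel):
        _, strains, truth = small_panel
        s = strains[2]
        t = s.temperatures[-1]
        entry = truth.entry(s.strain_id, t)
        pt = render_peak_table(truth, s.strain_id, t, noise_cv=0.0)
        profile = gc_quant.quantify_fames(pt)
        summary = fa.summarize_profile(profile.masses)
        truth_summary = fa.summarize_profile(entry.fa_fractions)
        assert summary.br_SFAs == pytest.approx(truth_summary.br_SFAs,
                                                abs=1e-9)
        assert summary.n_MUFAs == pytest.approx(truth_summary.n_MUFAs,
                                                abs=1e-9)
        assert summary.unknown_FAs == pytest.approx(
            truth_summary.unknown_FAs, abs=1e-9)


class TestSpectrumRendering:
    def test_clean_spectrum_matches_analytic_band_sum(self, small_panel):
        _, strains, truth = small_panel
        s = strains[0]
        t = s.temperatures[0]
        entry = truth.entry(s.strain_id, t)
        spectrum = render_spectrum(truth, s.strain_id, t,
                                   include_artifacts=False, noise_sd=0.0)
        idx = int(np.argmin(np.abs(spectrum.wavenumbers - 1656.0)))
        w0 = spectrum.wavenumbers[idx]
        expected = sum(
            amp * np.exp(-0.5 * ((w0 - c) / BAND_SIGMAS[c]) ** 2)
            for c, amp in entry.band_amplitudes.items()
        )
        assert spectrum.values[idx] == pytest.approx(expected, rel=1e-12)

    def test_fixed_seed_gives_bit_identical_spectra(self, small_panel):
        _, strains, truth = small_panel
        s = strains[0]
        t = s.temperatures[0]
        a = render_spectrum(truth, s.strain_id, t, noise_sd=0.01)
        b = render_spectrum(truth, s.strain_id, t, noise_sd=0.01)
        assert np.array_equal(a.values, b.values)

    def test_emsc_removes_the_generated_artifacts(self, small_panel):
        """Preprocessing a noiseless artifact spectrum recovers the same
        corrected spectrum as its artifact-free twin."""
        _, strains, truth = small_panel
        chosen = [(s.strain_id, t) for s in strains[:6]
                  for t in s.temperatures[:1]]
        with_art = SpectrumSet.from_spectra([
            render_spectrum(truth, sid, t, include_artifacts=True)
            for sid, t in chosen
        ])
        without = SpectrumSet.from_spectra([
            render_spectrum(truth, sid, t, include_artifacts=False)
            for sid, t in chosen
        ])
        # correct both against the clean set's mean so the comparison
        # shares one reference
        from coldchem.ftir import cut_regions, emsc_correct, emsc_fit, \
            savgol
        ref_set = cut_regions(savgol(without, deriv_order=2))
        reference = ref_set.matrix.mean(axis=0)
        art_set = cut_regions(savgol(with_art, deriv_order=2))
        corrected_art = emsc_correct(
            art_set, emsc_fit(art_set, reference=reference))
        corrected_clean = emsc_correct(
            ref_set, emsc_fit(ref_set, reference=reference))
        assert np.allclose(corrected_art.matrix,
                           corrected_clean.matrix, atol=1e-6)


def test_metadata_frame_layout(small_panel):
    config, strains, _ = small_panel
    meta = metadata_frame(strains)
    assert set(meta.columns) >= {
        "sample_id", "strain_id", "genus", "phylum", "gram",
        "lifestyle", "temperature", "bio_replicate",
    }
    expected_rows = sum(
        len(s.temperatures) * s.bio_replicates for s in strains
    )
    assert len(meta) == expected_rows
    assert meta["sample_id"].is_unique


def test_truth_ledger_json_round_trip(small_panel):
    _, _, truth = small_panel
    restored = SyntheticTruth.from_json(truth.to_json())
    assert restored.seed == truth.seed
    assert restored.entries.keys() == truth.entries.keys()
    key = next(iter(truth.entries))
    assert restored.entries[key].fa_fractions == \
        truth.entries[key].fa_fractions
    assert restored.artifacts == truth.artifacts


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        PanelConfig(strains_per_genus=0)
    with pytest.raises(ValueError):
        PanelConfig(roster=(GENUS_ROSTER[0], GENUS_ROSTER[0]))
    with pytest.raises(ValueError):
        PanelConfig(lipid_range=(0.2, 0.1))
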