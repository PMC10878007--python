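"""End-to-end runs: GC stage, FTIR stage, and the full pipeline.

Each run is fully determined by a :class:`RunConfig`; the resolved
config is written into the output directory alongside the tidy result
tables, so a run can be reproduced bit-for-bit from its own output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands, chemometrics, fa, gc_quant, io, synthetic
from .ftir import pipeline_pca, pipeline_ratio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_gc", "run_ftir", "run_all"]

GROUPINGS = ("all", "gram", "phylum", "genus", "temperature")

GC_CLASS_FEATURES = (
    "PUFAs", "n_SFAs", "br_SFAs", "n_MUFAs",
    "hydroxy_FAs", "cyclic_FAs", "unknown_FAs",
)


@dataclass
class RunConfig:
    """All stage parameters of a reproducible run.

    Paths are interpreted relative to the current working directory;
    the serialized copy written into ``outdir`` keeps them as given.
    """

    outdir: str = "."
    metadata: str = "metadata.tsv"
    peaks: str = "peaks.tsv"
    spectra: str = "spectra.tsv"
    spectra_meta: str = "spectra_meta.tsv"
    seed: int = 0
    # generator
    strains_per_genus: int = 2
    effect_size: float = 0.4
    noise_cv: float = 0.05
    noise_sd: float = 0.005
    # GC stage
    is_label: str = "C19:0"
    is_mass_mg: float = gc_quant.DEFAULT_IS_MASS_MG
    rrf_file: str | None = None
    minor_threshold_pct: float = 1.0
    # FTIR stage
    sg_window: int = 11
    sg_poly_order: int = 2
    ratio_deriv_order: int = 0
    lp_num: float = 1742.0
    lp_den: float = 1656.0
    pp_num: float = 1083.0
    pp_den: float = 1656.0
    band_mode: str = "local_extremum_in_window"
    band_halfwidth: float = 8.0
    n_components: int = 5
    groupings: tuple[str, ...] = GROUPINGS

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        payload["groupings"] = list(self.groupings)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "groupings" in payload:
            payload["groupings"] = tuple(payload["groupings"])
        return cls(**payload)


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, sep="\t", index=False, na_rep="")


def _load_rrf(config: RunConfig) -> gc_quant.RRFTable:
    if not config.rrf_file:
        return gc_quant.RRFTable()
    df = pd.read_csv(config.rrf_file, sep="\t")
    return gc_quant.RRFTable(
        factors=dict(zip(df["fa_label"], df["rrf"].astype(float)))
    )


def group_stats(
    values: pd.DataFrame,
    value_column: str,
    by: tuple[str, ...] = ("genus", "temperature"),
) -> pd.DataFrame:
    """Mean and standard deviation per group.

    The sd is reported only for groups with at least two members;
    singleton groups get a missing (absent) sd, not zero.
    """
    grouped = values.groupby(list(by), sort=True)[value_column]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1)
                      if len(s) >= 2 else np.nan, n="size")
    return out.reset_index()


def run_gc(
    config: RunConfig,
    metadata: pd.DataFrame | None = None,
    peak_tables: list[gc_quant.PeakTable] | None = None,
    write: bool = True,
) -> dict:
    """GC stage: quantification, lipid content, class sums, PCA.

    Samples whose quantification fails (e.g. missing internal standard)
    are collected in an error report; the run continues for the rest.
    """
    outdir = Path(config.outdir)
    if metadata is None:
        metadata = io.read_metadata(outdir / config.metadata)
    if peak_tables is None:
        peak_tables = io.read_peak_tables(
            outdir / config.peaks, metadata,
            is_label=config.is_label, is_mass_mg=config.is_mass_mg,
        )
    rrf = _load_rrf(config)

    tl_rows, weight_rows, summaries, errors = [], [], [], []
    for pt in peak_tables:
        try:
            profile = gc_quant.quantify_fames(pt, rrf)
            tl = gc_quant.total_lipid_content(profile, pt.biomass_dry_mg)
            summary = fa.summarize_profile(
                profile.masses,
                minor_threshold_pct=config.minor_threshold_pct,
                sample_id=pt.sample_id,
            )
        except (gc_quant.QuantificationError, ValueError) as exc:
            errors.append({"sample_id": pt.sample_id, "error": str(exc)})
            continue
        tl_rows.append({"sample_id": pt.sample_id, "total_lipid_pct": tl})
        percents = profile.percent()
        for label, mass in profile.masses.items():
            weight_rows.append({
                "sample_id": pt.sample_id, "fa_label": label,
                "mass_mg": mass, "percent": percents[label],
            })
        summaries.append(summary.as_dict())
    if errors:
        logger.warning("GC stage: %d samples failed quantification",
                       len(errors))
    if not tl_rows:
        raise ValueError("no sample could be quantified")

    tl_table = pd.DataFrame(tl_rows).merge(metadata, on="sample_id",
                                           how="left")
    class_table = pd.DataFrame(summaries)
    tl_stats = group_stats(tl_table, "total_lipid_pct")

    features = class_table.set_index("sample_id")[list(GC_CLASS_FEATURES)]
    scaled = chemometrics.autoscale(features)
    pca_result = chemometrics.pca(
        scaled, n_components=min(config.n_components,
                                 scaled.shape[0] - 1, scaled.shape[1])
    )
    explained = pd.DataFrame({
        "component": pca_result.scores.columns,
        "explained_variance_fraction":
            pca_result.explained_variance_fraction,
    })

    results = {
        "tl_table": tl_table,
        "fa_weights": pd.DataFrame(weight_rows),
        "fa_classes": class_table,
        "tl_group_stats": tl_stats,
        "gc_pca": pca_result,
        "gc_pca_explained": explained,
        "errors": pd.DataFrame(errors,
                               columns=["sample_id", "error"]),
    }
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        _write(tl_table, outdir, "total_lipid.tsv")
        _write(results["fa_weights"], outdir, "fa_weights.tsv")
        _write(class_table, outdir, "fa_classes.tsv")
        _write(tl_stats, outdir, "tl_group_stats.tsv")
        _write(pca_result.scores.reset_index(names="sample_id")
               .merge(metadata, on="sample_id", how="left"),
               outdir, "gc_pca_scores.tsv")
        _write(pca_result.loadings.reset_index(names="feature"),
               outdir, "gc_pca_loadings.tsv")
        _write(explained, outdir, "gc_pca_explained.tsv")
        _write(results["errors"], outdir, "gc_errors.tsv")
    return results


def run_ftir(
    config: RunConfig,
    metadata: pd.DataFrame | None = None,
    sset=None,
    tl_table: pd.DataFrame | None = None,
    write: bool = True,
) -> dict:
    """FTIR stage: both preprocessing paths, band ratios, PCA,
    and the grouped correlation of L/P against GC lipid content."""
    outdir = Path(config.outdir)
    if metadata is None:
        metadata = io.read_metadata(outdir / config.metadata)
    if sset is None:
        sset = io.read_spectra(outdir / config.spectra,
                               outdir / config.spectra_meta)
    if tl_table is None:
        tl_path = outdir / "total_lipid.tsv"
        if tl_path.exists():
            tl_table = pd.read_csv(tl_path, sep="\t")

    corrected = pipeline_pca(
        sset, window=config.sg_window, poly_order=config.sg_poly_order,
        drop_uncorrectable=True,
    )
    n_excluded = len(sset.metadata) - len(corrected.metadata)
    if n_excluded:
        logger.warning("FTIR stage: %d uncorrectable spectra excluded "
                       "from PCA", n_excluded)
    spectra_features = pd.DataFrame(
        corrected.matrix,
        index=pd.Index(range(corrected.matrix.shape[0])),
        columns=[f"{w:.3f}" for w in corrected.wavenumbers],
    )
    pca_result = chemometrics.pca(
        spectra_features,
        n_components=min(config.n_components,
                         spectra_features.shape[0] - 1),
    )
    explained = pd.DataFrame({
        "component": pca_result.scores.columns,
        "explained_variance_fraction":
            pca_result.explained_variance_fraction,
    })

    ratio_set = pipeline_ratio(
        sset, window=config.sg_window, poly_order=config.sg_poly_order,
        deriv_order=config.ratio_deriv_order,
    )
    ratio_results = bands.compute_ratios(
        ratio_set,
        lp_bands=(config.lp_num, config.lp_den),
        pp_bands=(config.pp_num, config.pp_den),
        mode=config.band_mode,
        search_halfwidth=config.band_halfwidth,
        magnitude=config.ratio_deriv_order == 2,
    )
    ratio_frame = bands.ratios_frame(ratio_results)
    by_sample = bands.average_technical_replicates(ratio_frame)
    by_sample = by_sample.merge(metadata, on="sample_id", how="left")

    correlations = pd.DataFrame()
    if tl_table is not None:
        paired = by_sample.merge(
            tl_table[["sample_id", "total_lipid_pct"]],
            on="sample_id", how="inner",
        )
        frames = []
        for grouping in config.groupings:
            res = chemometrics.pearson_by_group(
                paired, x="L_over_P", y="total_lipid_pct",
                grouping=None if grouping == "all" else grouping,
            )
            res.insert(0, "grouping", grouping)
            frames.append(res)
        correlations = pd.concat(frames, ignore_index=True)

    results = {
        "ftir_pca": pca_result,
        "ftir_pca_explained": explained,
        "band_ratios": ratio_frame,
        "band_ratios_by_sample": by_sample,
        "correlations": correlations,
        "n_uncorrectable": n_excluded,
    }
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        scores = pca_result.scores.copy()
        scores.insert(0, "sample_id",
                      corrected.metadata["sample_id"].to_numpy())
        scores.insert(1, "replicate",
                      corrected.metadata["replicate"].to_numpy())
        _write(scores, outdir, "ftir_pca_scores.tsv")
        _write(pca_result.loadings.reset_index(names="wavenumber"),
               outdir, "ftir_pca_loadings.tsv")
        _write(explained, outdir, "ftir_pca_explained.tsv")
        _write(ratio_frame, outdir, "band_ratios.tsv")
        _write(by_sample, outdir, "band_ratios_by_sample.tsv")
        if not correlations.empty:
            _write(correlations, outdir, "correlations.tsv")
    return results


def run_all(config: RunConfig) -> dict:
    """Generate the synthetic panel, write its inputs, run both stages."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel_config = synthetic.PanelConfig(
        strains_per_genus=config.strains_per_genus,
        effect_size=config.effect_size,
    )
    strains, truth = synthetic.generate_panel(panel_config,
                                              seed=config.seed)
    metadata = synthetic.metadata_frame(strains)
    metadata["biomass_dry_mg"] = panel_config.biomass_dry_mg
    tables, sset = synthetic.render_panel(
        strains, truth, noise_cv=config.noise_cv,
        noise_sd=config.noise_sd,
        biomass_dry_mg=panel_config.biomass_dry_mg,
    )

    io.write_metadata(metadata, outdir / config.metadata)
    io.write_peak_tables(tables, outdir / config.peaks)
    io.write_spectra(sset, outdir / config.spectra,
                     outdir / config.spectra_meta)
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.yaml").write_text(config.to_yaml())

    gc_results = run_gc(config, metadata=metadata, peak_tables=tables)
    ftir_results = run_ftir(
        config, metadata=metadata, sset=sset,
        tl_table=gc_results["tl_table"],
    )
    return {"strains": strains, "truth": truth,
            **gc_results, **ftir_results}
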