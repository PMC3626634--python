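"""End-to-end orchestration: cohort -> coherence -> graphs -> resilience -> stats.

A run takes either a directory of EDF files plus a metadata CSV
(subject_id, ASD, TSC, age) or a synthetic cohort spec, derives the full
per-subject measure set in every analysis band, and fits the two-way
age-adjusted group model to each measure.  Outputs are plain CSV tables
plus a JSON manifest (config hash, seed, package versions) so a rerun
with the same manifest reproduces byte-identical results.

Subject-level failures (too little usable data, unreadable files) are
logged and excluded rather than aborting the run; the run fails only when
fewer than two subjects per required subgroup survive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coherence import (DEFAULT_BANDS, FrequencyBand, WelchConfig,
                        band_coherence_matrices, inter_intra_ratio,
                        long_short_ratio, mean_coherence)
from .graph import build_graph, graph_metrics
from .io import PreprocessConfig, SubjectRejected, load_recording, preprocess, \
    read_segment_table
from .montage import ElectrodeMontage, build_standard_montage
from .resilience import hub_profile, random_failure, targeted_attack
from .stats import fit_ancova, results_grid
from .synthetic import SegmentedRecording, SyntheticCohortSpec, generate_cohort

__all__ = [
    "ResilienceConfig",
    "RunConfig",
    "derive_measures",
    "cohort_table",
    "run_pipeline",
    "MEASURES",
]


@dataclass(frozen=True)
class ResilienceConfig:
    k_max: int = 5
    replicates: int = 1000
    seed: int = 0
    hub_ranks: tuple[int, ...] = (1, 2, 3)


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one of ``edf_dir`` / ``synthetic`` is set."""

    out_dir: str = "cohgraph_run"
    edf_dir: str | None = None
    metadata_csv: str | None = None
    synthetic: SyntheticCohortSpec | None = None
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS
    welch: WelchConfig = field(default_factory=WelchConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    resilience: ResilienceConfig = field(default_factory=ResilienceConfig)

    def __post_init__(self):
        if (self.edf_dir is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input mode (edf_dir or synthetic) must be set")


def _measure_names(res_cfg: ResilienceConfig) -> list[str]:
    names = ["mean_coherence", "inter_intra_ratio", "long_short_ratio",
             "clustering", "path_length", "efficiency"]
    names += [f"targeted_k{k}" for k in range(1, res_cfg.k_max + 1)]
    names += [f"random_k{k}" for k in range(1, res_cfg.k_max + 1)]
    names += [f"hub{r}" for r in res_cfg.hub_ranks]
    return names


MEASURES = _measure_names(ResilienceConfig())


def derive_measures(recording: SegmentedRecording,
                    montage: ElectrodeMontage,
                    bands=DEFAULT_BANDS,
                    welch: WelchConfig = WelchConfig(),
                    res_cfg: ResilienceConfig = ResilienceConfig(),
                    ) -> dict[str, float]:
    """All per-subject measures, keyed ``<measure>__<band>``."""
    out: dict[str, float] = {}
    matrices = band_coherence_matrices(recording, bands, welch)
    for band_name, m in matrices.items():
        g = build_graph(m, nodes=montage.names)
        gm = graph_metrics(g)
        ta = targeted_attack(g, res_cfg.k_max)
        rf = random_failure(g, res_cfg.k_max, res_cfg.replicates,
                            seed=res_cfg.seed)
        hubs = hub_profile(g, res_cfg.hub_ranks)
        row = {
            "mean_coherence": mean_coherence(m),
            "inter_intra_ratio": inter_intra_ratio(m, montage),
            "long_short_ratio": long_short_ratio(m, montage),
            "clustering": gm.clustering_coefficient,
            "path_length": gm.characteristic_path_length,
            "efficiency": gm.global_efficiency,
        }
        for k, v in zip(ta.ks, ta.relative_efficiency):
            row[f"targeted_k{k}"] = v
        for k, v in zip(rf.ks, rf.relative_efficiency):
            row[f"random_k{k}"] = v
        for h in hubs:
            row[f"hub{h.rank}"] = h.normalized_degree
        for key, val in row.items():
            out[f"{key}__{band_name}"] = float(val)
    return out


def _gather_synthetic(cfg: RunConfig):
    recordings, meta = generate_cohort(cfg.synthetic)
    return recordings, meta


def _gather_edf(cfg: RunConfig, montage: ElectrodeMontage):
    meta = pd.read_csv(cfg.metadata_csv)
    edf_dir = Path(cfg.edf_dir)
    recordings = {}
    failures = {}
    for row in meta.itertuples():
        sid = str(row.subject_id)
        try:
            rec = load_recording(edf_dir / f"{sid}.edf", montage)
            seg_path = edf_dir / f"{sid}_segments.csv"
            bounds = (read_segment_table(seg_path)
                      if seg_path.exists() else None)
            recordings[sid] = preprocess(
                rec, cfg.preprocess, bounds, subject_id=sid,
                min_segment_duration=cfg.welch.window_seconds)
        except (SubjectRejected, ValueError, OSError) as exc:
            failures[sid] = str(exc)
    return recordings, meta, failures


def cohort_table(recordings: list[SegmentedRecording], meta: pd.DataFrame,
                 montage: ElectrodeMontage | None = None,
                 bands=DEFAULT_BANDS,
                 welch: WelchConfig = WelchConfig(),
                 res_cfg: ResilienceConfig = ResilienceConfig(),
                 ) -> pd.DataFrame:
    """Metadata plus all derived measures, one row per subject."""
    montage = montage or build_standard_montage()
    rows = []
    for rec, mrow in zip(recordings, meta.itertuples()):
        row = {"subject_id": mrow.subject_id}
        for col in meta.columns:
            if col != "subject_id":
                row[col] = getattr(mrow, col)
        row.update(derive_measures(rec, montage, bands, welch, res_cfg))
        rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    payload = asdict(cfg)
    payload.pop("out_dir", None)  # location does not affect the science
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run and write the artifact set under ``cfg.out_dir``.

    Artifacts: per-subject per-band coherence matrices (CSV), the cohort
    measure table, the Table-1-style p-value grid, the full ANCOVA
    coefficient table, and ``manifest.json``.
    """
    montage = build_standard_montage()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: dict[str, str] = {}

    if cfg.synthetic is not None:
        recordings, meta = _gather_synthetic(cfg)
        rec_list, meta_kept = recordings, meta
    else:
        recs, meta, failures = _gather_edf(cfg, montage)
        keep = meta["subject_id"].astype(str).isin(recs)
        meta_kept = meta[keep].reset_index(drop=True)
        rec_list = [recs[str(s)] for s in meta_kept["subject_id"]]

    for asd, tsc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        n_cell = int(((meta_kept["ASD"] == asd)
                      & (meta_kept["TSC"] == tsc)).sum())
        if n_cell < 2:
            raise RuntimeError(
                f"fewer than 2 surviving subjects in subgroup "
                f"ASD={asd}, TSC={tsc} (excluded: {failures})")

    mat_dir = out / "coherence_matrices"
    mat_dir.mkdir(exist_ok=True)
    for rec in rec_list:
        mats = band_coherence_matrices(rec, cfg.bands, cfg.welch)
        for band_name, m in mats.items():
            df = pd.DataFrame(m.values, index=montage.names,
                              columns=montage.names)
            df.to_csv(mat_dir / f"{rec.subject_id}_{band_name}.csv")

    table = cohort_table(rec_list, meta_kept, montage, cfg.bands,
                         cfg.welch, cfg.resilience)
    table.to_csv(out / "cohort_measures.csv", index=False)

    band_names = [b.name for b in cfg.bands]
    grid = results_grid(table, _measure_names(cfg.resilience), band_names)
    grid.to_csv(out / "stats_grid.csv", index=False)

    coef_rows = []
    for measure in _measure_names(cfg.resilience):
        for band in band_names:
            res = fit_ancova(table, f"{measure}__{band}", band=band)
            for term in ("intercept", "ASD", "TSC", "age"):
                coef_rows.append({
                    "measure": measure, "band": band, "term": term,
                    "estimate": res.params[term], "se": res.bse[term],
                    "t": res.tvalues[term],
                    "p_raw": res.pvalues[term],
                    "df_resid": res.df_resid})
    pd.DataFrame(coef_rows).to_csv(out / "ancova_coefficients.csv",
                                   index=False)

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": (cfg.synthetic.seed if cfg.synthetic is not None else None),
        "resilience_seed": cfg.resilience.seed,
        "n_subjects": len(rec_list),
        "excluded": failures,
        "versions": {
            "cohgraph": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"table": table, "grid": grid, "manifest": manifest,
            "out_dir": str(out)}
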