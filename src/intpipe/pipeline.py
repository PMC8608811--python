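"""Config-driven study pipeline.

Runs the full discovery/replication design from one YAML config:
per-subject INT maps, a voxelwise discovery t-map with cluster extraction,
ROI mean extraction everywhere, ROI-level group comparisons before FD
matching (discovery dataset excluded, to avoid double-dipping) and after FD
matching (discovery included), FD-INT correlations, symptom correlations
and sex/medication main-effect models, plus demographic balance checks.

ROIs are frozen after the discovery stage and reused unchanged in every
later comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from intpipe import inference, mapping, motion, synth, timescale

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSettings",
    "DatasetConfig",
    "PipelineConfig",
    "Dataset",
    "load_config",
    "load_dataset",
    "run_pipeline",
    "demographic_balance",
]

_KNOWN_RECORD_COLS = {"subject_id", "group", "sex", "age", "mean_fd", "cpz"}


@dataclass
class AnalysisSettings:
    p_thresh: float = 0.001
    connectivity: int = 18
    min_cluster_size: int = 5
    alpha_fd: float = 0.05
    bonferroni_m: int = 5
    include_lag0: bool = False
    min_group: int = 10
    max_lag: int | None = None
    ttest_variant: str = "pooled"


@dataclass
class DatasetConfig:
    name: str
    role: str
    tr: float
    sessions: list[int] | None = None
    manifest: str | None = None
    synthetic: dict | None = None

    def __post_init__(self) -> None:
        if self.role not in ("discovery", "replication"):
            raise ValueError(f"dataset {self.name!r}: role must be discovery|replication")
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError(
                f"dataset {self.name!r}: exactly one of manifest/synthetic required"
            )


@dataclass
class PipelineConfig:
    datasets: list[DatasetConfig]
    output_dir: Path
    seed: int = 0
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        roles = [d.role for d in self.datasets]
        if roles.count("discovery") != 1:
            raise ValueError("config must declare exactly one discovery dataset")


@dataclass
class Dataset:
    """In-memory dataset: one 4-D volume and one record row per subject."""

    name: str
    role: str
    tr: float
    session_lengths: list[int] | None
    volumes: list[np.ndarray]
    mask: np.ndarray
    records: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    datasets = [DatasetConfig(**entry) for entry in raw["datasets"]]
    analysis = AnalysisSettings(**raw.get("analysis", {}))
    return PipelineConfig(
        datasets=datasets,
        output_dir=Path(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        analysis=analysis,
    )


def build_cohort_spec(params: dict, seed: int) -> synth.CohortSpec:
    """Build a CohortSpec from a plain config dict (regions as center/size boxes)."""
    params = dict(params)
    region_specs = params.pop("planted_regions", [])
    grid_shape = tuple(params.pop("grid_shape"))
    regions = [
        synth.box_region(
            grid_shape,
            center=r["center"],
            size=r["size"],
            name=r.get("name", f"region{i+1}"),
            phi_control=r["phi_control"],
            phi_patient=r["phi_patient"],
        )
        for i, r in enumerate(region_specs)
    ]
    params.setdefault("seed", seed)
    return synth.CohortSpec(grid_shape=grid_shape, planted_regions=regions, **params)


def load_dataset(cfg: DatasetConfig, seed: int) -> Dataset:
    """Materialise one dataset, either synthetic (seeded) or from a manifest."""
    if cfg.synthetic is not None:
        params = dict(cfg.synthetic)
        params.setdefault("tr", cfg.tr)
        spec = build_cohort_spec(params, seed)
        cohort = synth.simulate_cohort(spec)
        return Dataset(
            name=cfg.name,
            role=cfg.role,
            tr=spec.tr,
            session_lengths=spec.session_lengths if spec.n_sessions > 1 else None,
            volumes=cohort.volumes,
            mask=spec.mask,
            records=cohort.records,
            affine=cohort.affine,
        )
    volumes, mask, records = synth.read_cohort(cfg.manifest)
    return Dataset(
        name=cfg.name,
        role=cfg.role,
        tr=cfg.tr,
        session_lengths=cfg.sessions,
        volumes=volumes,
        mask=mask,
        records=records,
    )


def demographic_balance(datasets: Sequence[Dataset]) -> pd.DataFrame:
    """Welch t on age and Yates chi-squared on sex, per dataset.

    A single-sex dataset gets its sex row marked ``skipped`` instead of a
    statistic (the age check still runs).
    """
    rows = []
    for ds in datasets:
        rec = ds.records
        hc, sz = rec[rec.group == "HC"], rec[rec.group == "SZ"]
        t, df, p = inference.welch_t(hc.age.to_numpy(), sz.age.to_numpy())
        rows.append(
            {"dataset": ds.name, "test": "age_welch_t", "statistic": t, "df": df, "p": p}
        )
        if rec.sex.nunique() < 2:
            logger.info("dataset %s is single-sex; sex balance test skipped", ds.name)
            rows.append(
                {
                    "dataset": ds.name,
                    "test": "sex_chi2_skipped",
                    "statistic": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                }
            )
            continue
        table = [
            [int((g.sex == "M").sum()), int((g.sex == "F").sum())] for g in (sz, hc)
        ]
        chi2, p = inference.chi2_2x2(table)
        rows.append(
            {"dataset": ds.name, "test": "sex_chi2", "statistic": chi2, "df": 1.0, "p": p}
        )
    return pd.DataFrame(rows)


def _int_maps(ds: Dataset, settings: AnalysisSettings) -> list[timescale.IntMap]:
    return [
        timescale.int_map(
            vol,
            ds.mask,
            ds.tr,
            sessions=ds.session_lengths,
            max_lag=settings.max_lag,
            include_lag0=settings.include_lag0,
            affine=ds.affine,
        )
        for vol in ds.volumes
    ]


def _roi_table(
    ds: Dataset, maps: list[timescale.IntMap], rois: list[mapping.RoiMask]
) -> pd.DataFrame:
    """Subject-by-ROI mean INT table joined with the subject records."""
    out = ds.records.copy()
    for roi in rois:
        out[roi.name] = [mapping.roi_mean(m, roi) for m in maps]
    return out


def _group_comparisons(
    roi_table: pd.DataFrame,
    rois: list[mapping.RoiMask],
    m: int,
    dataset: str,
    stage: str,
    double_dipping: bool = False,
) -> list[dict]:
    rows = []
    hc = roi_table[roi_table.group == "HC"]
    sz = roi_table[roi_table.group == "SZ"]
    for roi in rois:
        res = inference.compare_groups(hc[roi.name].to_numpy(), sz[roi.name].to_numpy(), m=m)
        rows.append(
            {
                "dataset": dataset,
                "stage": stage,
                "roi": roi.name,
                "n_hc": len(hc),
                "n_sz": len(sz),
                "mean_hc": float(hc[roi.name].mean()),
                "mean_sz": float(sz[roi.name].mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "p_bonf": res.p_bonf,
                "g": res.g,
                "double_dipping": double_dipping,
            }
        )
    return rows


def _fd_int_correlations(
    roi_table: pd.DataFrame, rois: list[mapping.RoiMask], m: int, dataset: str, stage: str
) -> list[dict]:
    rows = []
    for group in ("HC", "SZ"):
        sub = roi_table[roi_table.group == group]
        for roi in rois:
            try:
                r, p = inference.pearson_r(sub.mean_fd.to_numpy(), sub[roi.name].to_numpy())
            except ValueError:
                continue
            rows.append(
                {
                    "dataset": dataset,
                    "stage": stage,
                    "group": group,
                    "roi": roi.name,
                    "r": r,
                    "p": p,
                    "p_bonf": inference.bonferroni(p, m),
                }
            )
    return rows


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "seed": config.seed,
            "analysis": vars(config.analysis),
            "datasets": [
                {k: v for k, v in vars(d).items() if k != "synthetic"}
                | {"synthetic": bool(d.synthetic)}
                for d in config.datasets
            ],
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study design; returns the report dict (also written
    to ``<output_dir>/report.json`` with all tables as TSV next to it)."""
    settings = config.analysis
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    exclusions: list[str] = []

    def _stage(name: str, dataset: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed on dataset {dataset!r}: {exc}"
            ) from exc

    # stage 1: materialise datasets and compute INT maps
    datasets: list[Dataset] = []
    int_maps: dict[str, list[timescale.IntMap]] = {}
    for i, entry in enumerate(config.datasets):
        ds = _stage("load", entry.name, load_dataset, entry, seed=config.seed * 1009 + i)
        datasets.append(ds)
        maps = _stage("int_maps", ds.name, _int_maps, ds, settings)
        int_maps[ds.name] = maps
        n_degen = sum(m.n_degenerate for m in maps)
        if n_degen:
            exclusions.append(f"{ds.name}: {n_degen} degenerate voxels set to INT=0")
    discovery = next(ds for ds in datasets if ds.role == "discovery")

    # stage 2: discovery voxelwise map and frozen ROIs
    disc_maps = int_maps[discovery.name]
    disc_rec = discovery.records
    maps_hc = [m for m, g in zip(disc_maps, disc_rec.group) if g == "HC"]
    maps_sz = [m for m, g in zip(disc_maps, disc_rec.group) if g == "SZ"]
    stat = _stage(
        "voxelwise_ttest", discovery.name, mapping.voxelwise_ttest,
        maps_hc, maps_sz, variant=settings.ttest_variant,
    )
    clusters, rois, label_grid = _stage(
        "extract_clusters", discovery.name, mapping.extract_clusters,
        stat,
        p_thresh=settings.p_thresh,
        direction="a_gt_b",
        connectivity=settings.connectivity,
        min_cluster_size=settings.min_cluster_size,
    )
    cluster_table = pd.DataFrame(
        [
            {
                "label": c.label,
                "size": c.size,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_t": c.peak_t,
                "fdr_q_at_peak": c.fdr_q_at_peak,
            }
            for c in clusters
        ]
    )
    _write_tsv(cluster_table, out / "discovery_clusters.tsv")
    _save_nifti(stat.t, stat.affine, out / "discovery_tmap.nii.gz")
    _save_nifti(stat.p, stat.affine, out / "discovery_pmap.nii.gz")
    _save_nifti(label_grid.astype(np.int16), stat.affine, out / "discovery_roi_labels.nii.gz")

    if not rois:
        logger.warning("no supra-threshold clusters on the discovery dataset")

    # stage 3: ROI mean extraction everywhere
    roi_tables = {
        ds.name: _stage("roi_mean", ds.name, _roi_table, ds, int_maps[ds.name], rois)
        for ds in datasets
    }
    for name, table in roi_tables.items():
        _write_tsv(table, out / f"roi_means_{name}.tsv")

    # stage 4: pre-matching ROI comparisons (discovery excluded: double dipping)
    comparisons: list[dict] = []
    for ds in datasets:
        if not rois:
            break
        if ds.role == "discovery":
            comparisons.extend(
                _group_comparisons(
                    roi_tables[ds.name], rois, settings.bonferroni_m,
                    ds.name, "pre_matching", double_dipping=True,
                )
            )
            continue
        comparisons.extend(
            _group_comparisons(
                roi_tables[ds.name], rois, settings.bonferroni_m, ds.name, "pre_matching"
            )
        )

    # stage 5: FD matching per dataset + post-matching reanalysis (all datasets)
    fd_results: dict[str, dict] = {}
    kept_tables: dict[str, pd.DataFrame] = {}
    for ds in datasets:
        rec = ds.records
        hc = [
            motion.FdSummary(r.subject_id, r.mean_fd)
            for r in rec[rec.group == "HC"].itertuples()
        ]
        sz = [
            motion.FdSummary(r.subject_id, r.mean_fd)
            for r in rec[rec.group == "SZ"].itertuples()
        ]
        match = _stage(
            "fd_match", ds.name, motion.fd_match,
            hc, sz, alpha=settings.alpha_fd, min_group=settings.min_group,
        )
        fd_results[ds.name] = match.to_dict()
        removed = [s.subject_id for s in match.removed_hc + match.removed_sz]
        for sid in removed:
            exclusions.append(f"{ds.name}: {sid} removed by FD matching")
        kept = set(fd_results[ds.name]["kept_hc"]) | set(fd_results[ds.name]["kept_sz"])
        kept_tables[ds.name] = roi_tables[ds.name][
            roi_tables[ds.name].subject_id.isin(kept)
        ]
        if rois:
            comparisons.extend(
                _group_comparisons(
                    kept_tables[ds.name], rois, settings.bonferroni_m,
                    ds.name, "post_matching",
                )
            )
    with open(out / "fd_match.json", "w") as fh:
        json.dump(fd_results, fh, indent=2, sort_keys=True)
    comparison_table = pd.DataFrame(comparisons)
    _write_tsv(comparison_table, out / "roi_comparisons.tsv")

    # stage 6: FD-INT correlations before and after matching
    fd_corr: list[dict] = []
    if rois:
        for ds in datasets:
            fd_corr.extend(
                _fd_int_correlations(
                    roi_tables[ds.name], rois, settings.bonferroni_m, ds.name, "pre_matching"
                )
            )
            fd_corr.extend(
                _fd_int_correlations(
                    kept_tables[ds.name], rois, settings.bonferroni_m, ds.name, "post_matching"
                )
            )
    _write_tsv(pd.DataFrame(fd_corr), out / "fd_int_correlations.tsv")

    # stage 7: symptom correlations and sex/medication models (post-matching)
    symptom_rows: list[dict] = []
    model_rows: list[dict] = []
    for ds in datasets:
        table = kept_tables[ds.name]
        symptom_cols = [
            c
            for c in table.columns
            if c not in _KNOWN_RECORD_COLS and c not in {r.name for r in rois}
        ]
        sz_rows = table[table.group == "SZ"]
        for roi in rois:
            for col in symptom_cols:
                sub = sz_rows[[roi.name, col]].dropna()
                if len(sub) < 3:
                    continue
                try:
                    r, p = inference.pearson_r(sub[roi.name], sub[col])
                except ValueError:
                    continue
                symptom_rows.append(
                    {
                        "dataset": ds.name,
                        "roi": roi.name,
                        "symptom": col,
                        "n": len(sub),
                        "r": r,
                        "p": p,
                        "p_bonf": inference.bonferroni(p, settings.bonferroni_m),
                    }
                )
            # sex main effect + group controlling for sex
            if table.sex.nunique() >= 2:
                effects = inference.linear_main_effects(
                    table[roi.name].to_numpy(),
                    {"group": table.group, "sex": table.sex},
                )
                for term, (f, p) in effects.items():
                    model_rows.append(
                        {
                            "dataset": ds.name,
                            "roi": roi.name,
                            "model": "group+sex",
                            "term": term,
                            "F": f,
                            "p": p,
                        }
                    )
            else:
                exclusions.append(f"{ds.name}: single-sex; sex model skipped ({roi.name})")
            cpz = sz_rows[[roi.name, "cpz"]].dropna()
            if len(cpz) >= 4 and cpz.cpz.nunique() > 1:
                effects = inference.linear_main_effects(
                    cpz[roi.name].to_numpy(), {"cpz": cpz.cpz.to_numpy()}
                )
                f, p = effects["cpz"]
                model_rows.append(
                    {
                        "dataset": ds.name,
                        "roi": roi.name,
                        "model": "cpz",
                        "term": "cpz",
                        "F": f,
                        "p": p,
                    }
                )
    _write_tsv(pd.DataFrame(symptom_rows), out / "symptom_correlations.tsv")
    _write_tsv(pd.DataFrame(model_rows), out / "main_effects.tsv")

    # stage 8: demographic balance
    balance = demographic_balance(datasets)
    _write_tsv(balance, out / "demographic_balance.tsv")

    (out / "exclusions.log").write_text("\n".join(exclusions) + ("\n" if exclusions else ""))

    import scipy

    report = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": {
                "intpipe": __import__("intpipe").__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
        },
        "datasets": {
            ds.name: {"role": ds.role, "n_hc": int((ds.records.group == "HC").sum()),
                      "n_sz": int((ds.records.group == "SZ").sum())}
            for ds in datasets
        },
        "n_clusters": len(clusters),
        "clusters": cluster_table.to_dict(orient="records"),
        "roi_comparisons": comparison_table.to_dict(orient="records"),
        "fd_match": fd_results,
        "fd_int_correlations": fd_corr,
        "symptom_correlations": symptom_rows,
        "main_effects": model_rows,
        "demographic_balance": balance.to_dict(orient="records"),
        "exclusions": exclusions,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def _save_nifti(grid: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(grid), affine), path)
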