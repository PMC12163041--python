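"""End-to-end orchestration: cohort I/O, feature extraction, and the full run.

The pipeline mirrors the analysis flow: (optional) bandpass -> global delay /
dimension selection -> delay embedding per (subject, session, ROI) ->
Vietoris-Rips H0/H1 diagrams -> landscapes on shared grids -> subject feature
vectors; plus the temporal 24-per-ROI baseline; then fingerprinting, CCA and
supervised prediction.

All interchange is plain TSV + JSON.  A single master seed derives per-stage
seeds through ``derive_seed`` so a run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca as cca_mod
from . import predict as predict_mod
from .cohort import CohortSpec, generate_cohort
from .embedding import EmbeddingParams, bandpass, delay_embed, select_global_params
from .fingerprint import identify, identify_by_network
from .landscapes import assemble_features, global_grid, landscape
from .rips import landmark_subsample, rips_h0, rips_h1, warm_up
from .temporal import impute_feature_matrix, temporal_features

__all__ = [
    "RunConfig",
    "derive_seed",
    "read_timeseries_dir",
    "compute_embedding_params",
    "compute_diagrams",
    "landscape_features",
    "temporal_feature_matrix",
    "run_all",
]

_STAGES = ("simulate", "embed", "ph", "landscape", "baseline",
           "fingerprint", "cca", "predict")


def derive_seed(master: int, stage: str) -> int:
    """Per-stage seed from one master seed (stable, documented rule)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    ``tau``/``dim`` accept "auto" (global MI/FNN selection) or an integer.
    ``landmarks`` caps cloud size for H1 (0 disables subsampling).
    Unknown keys are rejected when loading from a mapping.
    """

    out_dir: str = "topobrain_run"
    in_dir: str | None = None  # read cohort from disk instead of simulating
    cohort: CohortSpec = field(default_factory=CohortSpec)
    band: tuple | None = (0.01, 0.08)
    tau: int | str = "auto"
    dim: int | str = "auto"
    max_lag: int = 50
    max_dim: int = 6
    param_subsample: int = 12
    max_eps: float | None = None  # None: per-cloud max pairwise distance
    landmarks: int = 100
    layers: int = 5
    bins: int = 20
    n_pc: int = 10
    n_perm: int = 999
    folds: int = 5
    repeats: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in data and isinstance(data["cohort"], dict):
            data["cohort"] = CohortSpec(**data["cohort"])
        if "band" in data and data["band"] is not None:
            data["band"] = tuple(data["band"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["networks"] = list(d["cohort"]["networks"])
        if d["band"] is not None:
            d["band"] = list(d["band"])
        return d


_FNAME = re.compile(r"sub-(\d+)_ses-(\d+)\.tsv$")


def read_timeseries_dir(path):
    """Read a cohort directory of ``sub-<i>_ses-<s>.tsv`` ROI x time files.

    Returns ``(series dict, network_labels or None)``.  Validates shape
    consistency, completeness (two sessions per subject), and absence of
    NaNs, naming the offending file and cell.
    """
    path = Path(path)
    series: dict = {}
    shape = None
    for f in sorted(path.glob("sub-*_ses-*.tsv")):
        m = _FNAME.search(f.name)
        if not m:
            continue
        subj, sess = int(m.group(1)), int(m.group(2))
        df = pd.read_csv(f, sep="\t")
        mat = df.to_numpy(dtype=float)
        if np.isnan(mat).any():
            r, c = np.argwhere(np.isnan(mat))[0]
            raise ValueError(f"NaN in {f.name} at row {r}, column {c}")
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise ValueError(
                f"{f.name} has shape {mat.shape}, expected {shape}"
            )
        series[(subj, sess)] = mat
    if not series:
        raise ValueError(f"no sub-*_ses-*.tsv files found under {path}")
    subjects = sorted({s for s, _ in series})
    incomplete = [s for s in subjects
                  if (s, 1) not in series or (s, 2) not in series]
    if incomplete:
        raise ValueError(f"subjects missing a session: {incomplete}")
    networks = None
    net_file = path / "networks.tsv"
    if net_file.exists():
        networks = pd.read_csv(net_file, sep="\t")["network"].tolist()
    return series, networks


def _preprocess(series: dict, fs: float, band) -> dict:
    if band is None:
        return series
    low, high = band
    return {k: bandpass(v, fs=fs, low=low, high=high) for k, v in series.items()}


def compute_embedding_params(series: dict, config: RunConfig) -> EmbeddingParams:
    """Resolve (tau, dim): fixed values from config or global auto-selection."""
    if config.tau != "auto" and config.dim != "auto":
        return EmbeddingParams(delay=int(config.tau), dimension=int(config.dim))
    pool = [row for mat in series.values() for row in mat]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auto = select_global_params(
            pool, max_lag=config.max_lag, max_dim=config.max_dim,
            subsample=config.param_subsample,
            seed=derive_seed(config.seed, "embed"),
        )
    tau = auto.delay if config.tau == "auto" else int(config.tau)
    dim = auto.dimension if config.dim == "auto" else int(config.dim)
    return EmbeddingParams(delay=tau, dimension=dim)


def compute_diagrams(series: dict, params: EmbeddingParams,
                     config: RunConfig) -> dict:
    """Embed every (subject, session, ROI) series and compute H0/H1 diagrams.

    Returns a dict keyed (subject, session, roi, dim).
    """
    warm_up()
    seed = derive_seed(config.seed, "ph")
    diagrams: dict = {}
    for (subj, sess), mat in sorted(series.items()):
        for roi in range(mat.shape[0]):
            cloud = delay_embed(mat[roi], params, source=(subj, sess, roi))
            if config.landmarks and cloud.n > config.landmarks:
                cloud = landmark_subsample(cloud, config.landmarks,
                                           seed=seed + roi)
            diagrams[(subj, sess, roi, 0)] = rips_h0(
                cloud, max_eps=config.max_eps, source=(subj, sess, roi))
            diagrams[(subj, sess, roi, 1)] = rips_h1(
                cloud, max_eps=config.max_eps, source=(subj, sess, roi))
    return diagrams


def landscape_features(diagrams: dict, config: RunConfig, grids: dict | None = None):
    """Landscapes on per-dimension global grids, assembled per subject-session.

    Returns ``(matrix, keys, layout, grids)``; pass ``grids`` back in to
    reuse a previously computed basis for held-out data.
    """
    dims = sorted({d for (_, _, _, d) in diagrams})
    rois = sorted({r for (_, _, r, _) in diagrams})
    if grids is None:
        grids = {
            d: global_grid(
                [dgm for (_, _, _, dd), dgm in diagrams.items() if dd == d],
                n_bins=config.bins,
            )
            for d in dims
        }
    lands = {
        key: landscape(dgm, k=config.layers, grid=grids[key[3]])
        for key, dgm in diagrams.items()
    }
    mat, keys, layout = assemble_features(lands, rois=rois, dims=dims)
    return mat, keys, layout, grids


def temporal_feature_matrix(series: dict):
    """24 features per ROI, concatenated ROI-major; NaNs median-imputed."""
    keys = sorted(series)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key in keys:
            mat = series[key]
            rows.append(np.concatenate([temporal_features(r) for r in mat]))
    return impute_feature_matrix(np.vstack(rows)), keys


def _session_split(mat: np.ndarray, keys: list):
    """Split an assembled matrix into aligned session-1 / session-2 blocks."""
    subjects = sorted({s for s, _ in keys})
    idx = {k: i for i, k in enumerate(keys)}
    s1 = mat[[idx[(s, 1)] for s in subjects]]
    s2 = mat[[idx[(s, 2)] for s in subjects]]
    return s1, s2, subjects


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write a manifest of stage outputs.

    Stages: simulate (or read) -> bandpass/embed -> persistence -> landscapes
    -> temporal baseline -> fingerprint -> CCA -> prediction.  Any stage
    failure aborts with the stage name; a partial manifest is persisted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    stage = "simulate"
    try:
        if config.in_dir is not None:
            series, networks = read_timeseries_dir(config.in_dir)
            cohort = None
            behaviors = group = None
            beh_file = Path(config.in_dir) / "behaviors.tsv"
            if beh_file.exists():
                behaviors = pd.read_csv(beh_file, sep="\t", index_col=0)
            grp_file = Path(config.in_dir) / "groups.tsv"
            if grp_file.exists():
                group = pd.read_csv(grp_file, sep="\t")["group"].to_numpy()
        else:
            spec = dataclasses.replace(
                config.cohort, seed=derive_seed(config.seed, "simulate"))
            cohort = generate_cohort(spec)
            series = cohort.series
            networks = cohort.network_labels
            behaviors = cohort.behaviors
            group = cohort.group
        manifest["stages"][stage] = {"n_series": len(series)}

        stage = "embed"
        tr = config.cohort.tr
        fs = 1.0 / tr
        pre = _preprocess(series, fs=fs, band=config.band)
        params = compute_embedding_params(pre, config)
        manifest["stages"][stage] = {"tau": params.delay, "dim": params.dimension}

        stage = "ph"
        diagrams = compute_diagrams(pre, params, config)
        diag_path = out / "diagrams.tsv"
        _write_diagrams(diagrams, diag_path)
        manifest["stages"][stage] = {"n_diagrams": len(diagrams)}

        stage = "landscape"
        pl_mat, pl_keys, layout, grids = landscape_features(diagrams, config)
        pl_path = out / "features_pl.tsv"
        _write_features(pl_mat, pl_keys, pl_path)
        (out / "grids.json").write_text(json.dumps(
            {str(d): g.tolist() for d, g in grids.items()}))
        manifest["stages"][stage] = {"n_features": pl_mat.shape[1]}

        stage = "baseline"
        tmp_mat, tmp_keys = temporal_feature_matrix(pre)
        _write_features(tmp_mat, tmp_keys, out / "features_temporal.tsv")
        manifest["stages"][stage] = {"n_features": tmp_mat.shape[1]}

        stage = "fingerprint"
        fp = {}
        pl1, pl2, _ = _session_split(pl_mat, pl_keys)
        for name, db, tg in [
            ("pl_h0", *(m[:, np.concatenate([layout.columns_for(r, 0) for r in layout.rois])] for m in (pl1, pl2))),
            ("pl_h1", *(m[:, np.concatenate([layout.columns_for(r, 1) for r in layout.rois])] for m in (pl1, pl2))),
            ("pl_both", pl1, pl2),
        ]:
            fp[name] = identify(db, tg).accuracy
        t1, t2, _ = _session_split(tmp_mat, tmp_keys)
        fp["temporal"] = identify(t1, t2).accuracy
        if networks is not None:
            per_net = identify_by_network(pl1, pl2, networks, layout)
            fp["per_network"] = {k: v.accuracy for k, v in per_net.items()}
        manifest["stages"][stage] = fp

        stage = "cca"
        if behaviors is not None:
            Yf, _ = cca_mod.filter_behaviors(behaviors)
            Yr = cca_mod.deconfound(Yf.to_numpy(dtype=float))
            res = cca_mod.cca_first_mode(
                pl1, Yr, n_pc=min(config.n_pc, Yr.shape[1]),
                n_perm=config.n_perm, seed=derive_seed(config.seed, "cca"))
            manifest["stages"][stage] = {"r1": res.r1, "p_perm": res.p_perm}
            np.savetxt(out / "cca_perm_null.tsv", res.perm_null, delimiter="\t")
            if networks is not None:
                contrib = cca_mod.roi_contributions(pl1, layout, res, networks)
                contrib.roi_table.to_csv(out / "cca_roi_contributions.tsv",
                                         sep="\t", index=False)
                contrib.network_table.to_csv(out / "cca_network_summary.tsv",
                                             sep="\t", index=False)

        stage = "predict"
        if group is not None:
            seed_p = derive_seed(config.seed, "predict")
            counts = np.bincount(np.asarray(group).astype(int))
            folds = min(config.folds, int(counts[counts > 0].min()))
            auc_pl = predict_mod.classify_binary(
                pl1, group, n_folds=folds, seed=seed_p,
                n_pc=config.n_pc).metrics[0]
            auc_tmp = predict_mod.classify_binary(
                t1, group, n_folds=folds, seed=seed_p,
                n_pc=config.n_pc).metrics[0]
            manifest["stages"][stage] = {"auc_pl": auc_pl, "auc_temporal": auc_tmp}
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_diagrams(diagrams: dict, path: Path) -> None:
    rows = []
    for (subj, sess, roi, dim), dgm in sorted(diagrams.items()):
        for b, d in dgm.pairs:
            rows.append((subj, sess, roi, dim, b, d, dgm.max_eps))
    pd.DataFrame(rows, columns=["subject", "session", "roi", "dim",
                                "birth", "death", "max_eps"]).to_csv(
        path, sep="\t", index=False)


def _write_features(mat: np.ndarray, keys: list, path: Path) -> None:
    df = pd.DataFrame(mat)
    df.insert(0, "session", [s for _, s in keys])
    df.insert(0, "subject", [s for s, _ in keys])
    df.to_csv(path, sep="\t", index=False)
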