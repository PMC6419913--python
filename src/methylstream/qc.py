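"""Per-sample quality control for methylation-array stores.

Implements the sample-level screens applied before an EWAS:

* ``outlyx`` — unsupervised multivariate outlier detection on a random
  probe subset, built to resist masking (outliers hiding each other)
  and swamping (good samples dragged into flags): a consensus of a
  robust principal-component outlyingness score and Tukey IQR fences on
  the first two PCs.
* ``bscon`` — bisulfite-conversion efficiency (ideally 100%) from the
  array's conversion control probes; samples below ~85% indicate
  incomplete conversion.
* ``qual`` — "normalization violence": per-sample RMSD between raw and
  normalized betas; arrays needing RMSD > 0.05 of adjustment are suspect.
* ``pca_random`` — exact PCA on a seeded random probe subset (a few
  percent of probes suffices for sample-level structure).
* ``predict_sex`` — 2-means clustering of PC scores, which on
  sex-chromosome probes separates males and females.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .store import MethylStore, StoreError

__all__ = [
    "QCReport",
    "outlyx",
    "bscon",
    "qual",
    "qual_store",
    "pca_random",
    "predict_sex",
    "run_qc",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {
    "outlyx_score": 0.5,
    "outlyx_iqr_mult": 2.0,
    "bscon_min_pct": 85.0,
    "qual_max_rmsd": 0.05,
}

BC_CATEGORIES = ("BISULFITE CONVERSION I", "BISULFITE CONVERSION II")


@dataclass
class QCReport:
    """Per-sample QC metrics plus the thresholds and seeds that produced
    them; ``failed`` lists samples the default recipe would drop."""

    frame: pd.DataFrame
    thresholds: dict
    seed: int | None = None

    @property
    def failed(self) -> list[str]:
        f = self.frame
        mask = pd.Series(False, index=f.index)
        if "outlyx_flag" in f:
            mask |= f["outlyx_flag"].fillna(False).astype(bool)
        if "bscon_pct" in f:
            mask |= f["bscon_pct"] < self.thresholds["bscon_min_pct"]
        if "qual_rmsd" in f:
            mask |= f["qual_rmsd"] > self.thresholds["qual_max_rmsd"]
        return f.loc[mask, "sample_id"].tolist()

    def write(self, csv_path: str) -> None:
        self.frame.to_csv(csv_path, index=False)
        sidecar = str(csv_path) + ".json"
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump({"thresholds": self.thresholds, "seed": self.seed}, fh, indent=2)


# -- subsampled PCA ----------------------------------------------------


def _subset_rows(source, n_probes: int, seed: int) -> np.ndarray:
    """Seeded random probe subset as a (samples x probes) dense matrix."""
    if isinstance(source, MethylStore):
        P = source.n_probes
        n_probes = min(n_probes, P)
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(P, size=n_probes, replace=False))
        block = source._dataset("betas")[rows, :]
        from . import _memory

        _memory.track(block.size)
        return block.T
    X = np.asarray(source, dtype=np.float64)
    P = X.shape[0]
    n_probes = min(n_probes, P)
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(P, size=n_probes, replace=False))
    return X[rows].T


def _pca_exact(data_sp: np.ndarray, k: int, center: bool, scale: bool):
    """Exact SVD PCA of a (samples x probes) matrix with a deterministic
    sign convention; returns (scores S x k, variance fractions)."""
    nan_rows = np.isnan(data_sp).any(axis=0)
    if nan_rows.any():
        warnings.warn(
            f"excluding {int(nan_rows.sum())} probes with missing values from PCA",
            stacklevel=3,
        )
        data_sp = data_sp[:, ~nan_rows]
    if data_sp.shape[1] < k:
        raise StoreError(f"fewer than k={k} usable probes after NaN exclusion")
    X = data_sp - data_sp.mean(axis=0) if center else data_sp.copy()
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    total_var = float((X**2).sum())
    scale = max(1.0, float(np.abs(data_sp).max()))
    if total_var <= X.size * (np.finfo(float).eps * scale) ** 2:
        raise StoreError("constant matrix: PCA undefined (zero variance)")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    k = min(k, len(s))
    scores = U[:, :k] * s[:k]
    var_frac = (s[:k] ** 2) / total_var
    return scores, var_frac


def pca_random(
    source,
    n_probes: int = 5000,
    k: int = 2,
    seed: int = 0,
    center: bool = True,
    scale: bool = False,
):
    """PCA of the beta matrix restricted to a seeded random probe subset.

    ``source`` is a MethylStore (betas assay) or a probe-major array.
    Probes containing any NaN are excluded (with a warning).  Returns
    (scores (S, k), variance fractions (k,)).
    """
    data = _subset_rows(source, n_probes, seed)
    return _pca_exact(data, k, center, scale)


# -- outlyx ------------------------------------------------------------


def outlyx(
    source,
    n_probes: int = 2000,
    iqr_mult: float = 2.0,
    outlier_threshold: float = 0.5,
    seed: int = 0,
    k: int = 2,
) -> pd.DataFrame:
    """Unsupervised per-sample outlier detection on a random probe subset.

    Two complementary detectors run on the top-k PC scores: (a) a
    robust outlyingness score — componentwise median/MAD-standardized
    distance mapped through the chi-square CDF into [0, 1] — and (b)
    Tukey fences (``iqr_mult`` x IQR beyond the quartiles) on PC1/PC2.
    A sample is flagged only when both agree, which keeps single
    detectors' false alarms out and, because both are built from
    medians/quartiles, resists masking and swamping.
    """
    data = _subset_rows(source, n_probes, seed)  # samples x probes
    S = data.shape[0]
    if S < 10:
        raise StoreError("outlyx requires at least 10 samples")
    nan_cols = np.isnan(data).any(axis=0)
    data = data[:, ~nan_cols]
    if data.shape[1] < k:
        raise StoreError(f"fewer than k={k} usable probes")

    # one-step reweighting: refit the PC basis and the robust location /
    # scale / fences on currently-unflagged samples only, projecting every
    # sample onto the clean basis.  A flagged sample therefore has no
    # leverage on the statistics that judge the others, which is what
    # makes the flag set stable under its removal.
    # flags only ever grow ("peeling"): a sample flagged at any round
    # stays out of the fitting set, and iteration stops when a round adds
    # nothing — so the flag set is a fixed point and survivors' verdicts
    # do not change when flagged samples are removed from the input.
    flags = np.zeros(S, dtype=bool)
    score = np.zeros(S)
    detected_score = np.zeros(S)
    for _ in range(S):
        clean = ~flags
        if clean.sum() < max(10, k + 1):
            break
        mean = data[clean].mean(axis=0)
        Xc = data - mean
        if float((Xc[clean] ** 2).sum()) <= Xc[clean].size * (
            np.finfo(float).eps * max(1.0, float(np.abs(data).max()))
        ) ** 2:
            raise StoreError("constant matrix: outlyx undefined (zero variance)")
        _, _, Vt = np.linalg.svd(Xc[clean], full_matrices=False)
        scores_pc = Xc @ Vt[:k].T
        ref = scores_pc[clean]
        med = np.median(ref, axis=0)
        mad = stats.median_abs_deviation(ref, axis=0, scale="normal")
        mad = np.where(mad > 0, mad, 1e-12)
        d2 = (((scores_pc - med) / mad) ** 2).sum(axis=1)
        score = stats.chi2.cdf(d2, df=k)
        flag_a = score > outlier_threshold
        q1, q3 = np.percentile(ref, [25, 75], axis=0)
        iqr = q3 - q1
        lo, hi = q1 - iqr_mult * iqr, q3 + iqr_mult * iqr
        flag_b = ((scores_pc < lo) | (scores_pc > hi)).any(axis=1)
        new = flag_a & flag_b & ~flags
        if not new.any():
            break
        detected_score[new] = score[new]
        flags |= new
    # flagged samples report the score that triggered them; the rest the
    # final clean-basis score
    score = np.where(flags, detected_score, score)

    sample_ids = (
        source.sample_ids if isinstance(source, MethylStore) else list(range(S))
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "outlyx_score": score,
            "outlyx_flag": flags,
        }
    )


# -- bscon -------------------------------------------------------------


def bscon(store: MethylStore) -> pd.Series:
    """Per-sample bisulfite-conversion percentage from control probes.

    Type II conversion controls read red/(red+green) per probe; Type I
    controls pair converted/unconverted beads (by order, within their
    designated channel) and read converted/(converted+unconverted) on
    that channel.  The sample value is 100 x the median over all
    conversion control probes — 100% for complete conversion.
    """
    ctrl = store.control_probes
    if len(ctrl) == 0:
        raise StoreError("store has no control probes")
    cats = ctrl.get("control_category", pd.Series("", index=ctrl.index)).fillna("")
    block = store.control_block  # (C, S, 2) channels (green, red)
    S = block.shape[1]
    convs: list[np.ndarray] = []

    ix2 = np.flatnonzero((cats == BC_CATEGORIES[1]).to_numpy())
    for i in ix2:
        green, red = block[i, :, 0], block[i, :, 1]
        with np.errstate(invalid="ignore"):
            convs.append(np.where(green + red > 0, red / (green + red), np.nan))

    bc1 = ctrl[cats == BC_CATEGORIES[0]]
    if len(bc1):
        if "role" not in bc1.columns:
            raise StoreError(
                "Type I conversion controls need a converted/unconverted role column"
            )
        for channel, grp in bc1.groupby(bc1["channel"].fillna("Grn")):
            ch = 1 if str(channel).lower().startswith("r") else 0
            conv_rows = grp.index[grp["role"].str.lower().str.startswith("c")]
            unconv_rows = grp.index[grp["role"].str.lower().str.startswith("u")]
            pos = {pid: i for i, pid in enumerate(ctrl["probe_id"])}
            for rc, ru in zip(conv_rows, unconv_rows):
                c_int = block[pos[ctrl.loc[rc, "probe_id"]], :, ch]
                u_int = block[pos[ctrl.loc[ru, "probe_id"]], :, ch]
                with np.errstate(invalid="ignore"):
                    convs.append(
                        np.where(c_int + u_int > 0, c_int / (c_int + u_int), np.nan)
                    )
    if not convs:
        raise StoreError("no bisulfite-conversion control probes present")
    mat = np.vstack(convs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pct = 100.0 * np.nanmedian(mat, axis=0)
    return pd.Series(pct, index=store.sample_ids, name="bscon_pct")


# -- qual --------------------------------------------------------------


def qual(
    raw_betas: np.ndarray,
    normalized_betas: np.ndarray,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-sample normalization violence: columnwise RMSD (and mean
    absolute deviation) between raw and normalized betas, NaN pairs
    dropped; flag fires when RMSD exceeds ``cutoff``."""
    raw = np.asarray(raw_betas, dtype=np.float64)
    norm = np.asarray(normalized_betas, dtype=np.float64)
    if raw.shape != norm.shape:
        raise StoreError(f"shape mismatch: {raw.shape} vs {norm.shape}")
    diff = norm - raw
    valid = ~np.isnan(diff)
    n = valid.sum(axis=0)
    sq = np.where(valid, diff**2, 0.0).sum(axis=0)
    ab = np.where(valid, np.abs(diff), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmsd = np.sqrt(sq / n)
        mad = ab / n
    return pd.DataFrame(
        {"qual_rmsd": rmsd, "qual_mad": mad, "qual_flag": rmsd > cutoff}
    )


def qual_store(
    store: MethylStore,
    raw_array: str = "betas",
    norm_array: str = "betas_norm",
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Streaming qual over store assays (row blocks; bounded memory)."""
    S = store.n_samples
    sq = np.zeros(S)
    ab = np.zeros(S)
    n = np.zeros(S)
    for r0, raw in store.iter_row_blocks(raw_array):
        norm = store.read_block(norm_array, (r0, r0 + raw.shape[0]), (0, S))
        diff = norm - raw
        valid = ~np.isnan(diff)
        n += valid.sum(axis=0)
        sq += np.where(valid, diff**2, 0.0).sum(axis=0)
        ab += np.where(valid, np.abs(diff), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmsd = np.sqrt(sq / n)
        mad = ab / n
    out = pd.DataFrame(
        {"qual_rmsd": rmsd, "qual_mad": mad, "qual_flag": rmsd > cutoff}
    )
    out.insert(0, "sample_id", store.sample_ids)
    return out


# -- sex prediction ----------------------------------------------------


def predict_sex(
    pc_scores: np.ndarray,
    reported_sex: pd.Series | None = None,
    seed: int = 0,
) -> pd.Series:
    """Guess sample sex by 2-means clustering of the first two PC scores.

    Cluster labels are mapped to M/F by the majority of ``reported_sex``
    within each cluster when available, otherwise returned as cluster
    ids.  Degenerate clusterings yield "unknown" for all samples.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(pc_scores, dtype=np.float64)[:, :2]
    S = X.shape[0]
    if S < 4:
        return pd.Series(["unknown"] * S)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    if len(np.unique(labels)) < 2:
        return pd.Series(["unknown"] * S)
    names = {0: "cluster0", 1: "cluster1"}
    if reported_sex is not None:
        rep = pd.Series(reported_sex).reset_index(drop=True)
        for lab in (0, 1):
            votes = rep[(labels == lab) & rep.isin(["M", "F"])]
            if len(votes):
                names[lab] = votes.mode().iloc[0]
        if names[0] == names[1]:
            names = {0: "cluster0", 1: "cluster1"}
    return pd.Series([names[l] for l in labels])


# -- combined report ---------------------------------------------------


def run_qc(
    store: MethylStore,
    seed: int = 0,
    n_probes: int = 2000,
    thresholds: dict | None = None,
    norm_array: str | None = None,
) -> QCReport:
    """Full per-sample QC: outlyx, bscon, PCA scores, sex guess, and —
    when a normalized assay is present — qual."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    report = outlyx(
        store,
        n_probes=n_probes,
        iqr_mult=th["outlyx_iqr_mult"],
        outlier_threshold=th["outlyx_score"],
        seed=seed,
    )
    try:
        report["bscon_pct"] = bscon(store).to_numpy()
    except StoreError:
        pass
    scores, _ = pca_random(store, n_probes=n_probes, k=2, seed=seed)
    report["pc1"] = scores[:, 0]
    report["pc2"] = scores[:, 1]

    manifest = store.probe_index
    chrom = manifest.get("chromosome", pd.Series("", index=manifest.index)).astype(str)
    sex_rows = np.flatnonzero(
        chrom.str.upper().str.replace("CHR", "", regex=False).isin(["X", "Y"]).to_numpy()
    )
    reported = None
    samples = store.sample_index
    if "reported_sex" in samples.columns:
        reported = samples["reported_sex"]
    if len(sex_rows) >= 2:
        block = store._dataset("betas")[np.sort(sex_rows), :]
        from . import _memory

        _memory.track(block.size)
        try:
            sex_scores, _ = _pca_exact(block.T, k=2, center=True, scale=False)
            report["predicted_sex"] = predict_sex(sex_scores, reported, seed=seed).to_numpy()
        except StoreError:
            report["predicted_sex"] = "unknown"
    else:
        report["predicted_sex"] = predict_sex(scores, reported, seed=seed).to_numpy()

    if norm_array and store.has_array(norm_array):
        q = qual_store(store, "betas", norm_array, cutoff=th["qual_max_rmsd"])
        report = report.merge(q, on="sample_id")
    return QCReport(frame=report, thresholds=th, seed=seed)
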