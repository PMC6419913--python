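"""Probewise EWAS and bump hunting over methylation stores.

``ewas_probewise`` fits, per CpG probe, an ordinary least-squares model
of beta on the design matrix and reports the target coefficient with a
two-sided t-test, streaming probes in bounded row blocks; results are
identical for any block size or worker count.  Benjamini-Hochberg FDR
is appended.

``bumphunt`` looks for differentially methylated regions: probewise
effects are smoothed by a centered running mean within positional
clusters (probes closer than ``max_gap``), candidate bumps are maximal
runs of |smoothed effect| >= cutoff, and significance comes from
permuting the target variable across samples — the family-wise p-value
of a bump is the fraction of permutations whose largest null bump area
reaches the observed area, with the observed statistic counted in the
null (so p >= 1/(n_perm+1)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .store import MethylStore, StoreError

__all__ = [
    "ewas_probewise",
    "cluster_probes",
    "find_bumps",
    "bumphunt",
    "write_bumps_bed",
]


def _design_matrix(design: pd.DataFrame, target: str,
                   covariates: list[str] | None = None) -> tuple[np.ndarray, int]:
    """Build (X, target column index); intercept prepended, rank-checked."""
    if target not in design.columns:
        raise StoreError(f"target column {target!r} not in design")
    cols = [target] + [c for c in (covariates or []) if c != target]
    X = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(dtype=np.float64) for c in cols]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StoreError("design matrix is rank-deficient (collinear columns)")
    return X, 1  # target sits after the intercept


def _ols_block(Y: np.ndarray, X: np.ndarray, t_ix: int) -> np.ndarray:
    """OLS per row of Y (probes x samples) on common X; returns
    (effect, se, t, p, n) rows. NaN-containing probes fall back to a
    per-probe fit on their complete samples."""
    P, S = Y.shape
    d = X.shape[1]
    out = np.full((P, 5), np.nan)
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    c_tt = XtX_inv[t_ix, t_ix]
    clean = ~np.isnan(Y).any(axis=1)
    if clean.any():
        Yc = Y[clean]
        coefs = Yc @ H.T
        resid = Yc - coefs @ X.T
        dof = S - d
        sigma2 = (resid**2).sum(axis=1) / dof
        se = np.sqrt(sigma2 * c_tt)
        eff = coefs[:, t_ix]
        with np.errstate(invalid="ignore", divide="ignore"):
            tval = eff / se
        pval = 2 * stats.t.sf(np.abs(tval), dof)
        out[clean] = np.column_stack([eff, se, tval, pval, np.full(eff.shape, S)])
    for i in np.flatnonzero(~clean):
        ok = ~np.isnan(Y[i])
        n = int(ok.sum())
        if n <= d:
            out[i] = [np.nan, np.nan, np.nan, np.nan, n]
            continue
        Xi = X[ok]
        XtX_i = Xi.T @ Xi
        if np.linalg.matrix_rank(XtX_i) < d:
            out[i] = [np.nan, np.nan, np.nan, np.nan, n]
            continue
        inv = np.linalg.inv(XtX_i)
        coef = inv @ Xi.T @ Y[i, ok]
        resid = Y[i, ok] - Xi @ coef
        sigma2 = (resid**2).sum() / (n - d)
        se = np.sqrt(sigma2 * inv[t_ix, t_ix])
        tval = coef[t_ix] / se if se > 0 else np.nan
        pval = 2 * stats.t.sf(abs(tval), n - d) if np.isfinite(tval) else np.nan
        out[i] = [coef[t_ix], se, tval, pval, n]
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    from statsmodels.stats.multitest import multipletests

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def ewas_probewise(
    source,
    design: pd.DataFrame,
    target: str,
    covariates: list[str] | None = None,
    rows_per_block: int | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Probewise OLS of beta on the design; per-probe effect, SE,
    t statistic, two-sided p, n used, and BH-FDR.

    ``source`` is a MethylStore (betas assay, streamed in row blocks
    under the memory cap) or a probe-major array/frame.
    """
    X, t_ix = _design_matrix(design, target, covariates)
    if isinstance(source, MethylStore):
        if len(design) != source.n_samples:
            raise StoreError("design rows do not match store samples")
        probe_ids = source.probe_ids
        blocks = source.iter_row_blocks("betas", rows_per_block)
    else:
        Y = np.asarray(source, dtype=np.float64)
        if len(design) != Y.shape[1]:
            raise StoreError("design rows do not match sample columns")
        probe_ids = (
            list(source.index) if isinstance(source, pd.DataFrame)
            else list(range(Y.shape[0]))
        )
        blocks = [(0, Y)]

    parts: list[tuple[int, np.ndarray]] = []
    if n_workers > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_workers) as ex:
            futs = [(r0, ex.submit(_ols_block, blk, X, t_ix)) for r0, blk in blocks]
            parts = [(r0, f.result()) for r0, f in futs]
    else:
        parts = [(r0, _ols_block(blk, X, t_ix)) for r0, blk in blocks]
    parts.sort(key=lambda t: t[0])
    res = np.vstack([p for _, p in parts])
    out = pd.DataFrame(
        res, columns=["effect", "se", "t", "p", "n"],
    )
    out.insert(0, "probe_id", probe_ids)
    out["n"] = out["n"].fillna(0).astype(int)
    out["fdr"] = _bh_fdr(out["p"].to_numpy())
    return out


# -- clustering and bumps ----------------------------------------------


def cluster_probes(manifest: pd.DataFrame, max_gap: int = 500) -> pd.Series:
    """Assign positional cluster ids: adjacent probes on one chromosome
    within ``max_gap`` bases share a cluster.  Ids are 1-based, stable
    across runs (assigned in chromosome-of-first-appearance, then
    position order)."""
    assay = manifest[~manifest.get("is_control", False).astype(bool)]
    if assay["position"].isna().any() or (assay["position"] < 1).any():
        raise StoreError("manifest has missing positions for assay probes")
    cluster = pd.Series(0, index=assay["probe_id"], dtype=int, name="cluster")
    next_id = 1
    for chrom in assay["chromosome"].drop_duplicates():
        sub = assay[assay["chromosome"] == chrom].sort_values(
            "position", kind="stable"
        )
        pos = sub["position"].to_numpy()
        ids = np.empty(len(sub), dtype=int)
        for i in range(len(sub)):
            if i == 0 or pos[i] - pos[i - 1] > max_gap:
                cur = next_id
                next_id += 1
            ids[i] = cur
        cluster.loc[sub["probe_id"]] = ids
    return cluster


def _smooth_cluster(effects: np.ndarray, span: int) -> np.ndarray:
    """Centered running mean of window ``span`` with edge shrink;
    vectors shorter than the span are returned unsmoothed."""
    n = len(effects)
    if n < span or span <= 1:
        return effects.copy()
    h = span // 2
    csum = np.concatenate([[0.0], np.cumsum(effects)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


class _BumpEngine:
    """Precomputed cluster geometry for repeated bump searches (the
    permutation loop re-smooths thousands of effect vectors)."""

    def __init__(self, manifest: pd.DataFrame, clusters: pd.Series,
                 cutoff: float, smooth_span: int):
        if cutoff <= 0:
            raise StoreError("cutoff must be positive")
        assay = manifest[~manifest.get("is_control", False).astype(bool)].reset_index(
            drop=True
        )
        self.assay = assay
        self.cutoff = cutoff
        self.span = smooth_span
        pos = assay["position"].to_numpy()
        cl = clusters.reindex(assay["probe_id"]).to_numpy()
        self.members: list[tuple[int, np.ndarray]] = []
        for cid in pd.unique(cl):
            ix = np.flatnonzero(cl == cid)
            ix = ix[np.argsort(pos[ix], kind="stable")]
            self.members.append((int(cid), ix))

    def max_area(self, effects: np.ndarray) -> float:
        best = 0.0
        for _, ix in self.members:
            sm = _smooth_cluster(np.nan_to_num(effects[ix]), self.span)
            above = np.abs(sm) >= self.cutoff
            if not above.any():
                continue
            # areas of maximal runs via cumulative-sum differencing
            edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            csum = np.concatenate([[0.0], np.cumsum(np.abs(sm))])
            areas = csum[ends] - csum[starts]
            best = max(best, float(areas.max()))
        return best

    def bumps(self, effects: np.ndarray) -> pd.DataFrame:
        assay = self.assay
        pos = assay["position"].to_numpy()
        rows = []
        for cid, ix in self.members:
            sm = _smooth_cluster(np.nan_to_num(effects[ix]), self.span)
            above = np.abs(sm) >= self.cutoff
            if not above.any():
                continue
            edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
            for i, j in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
                run, seg = ix[i:j], sm[i:j]
                rows.append(
                    {
                        "chromosome": assay["chromosome"].iloc[run[0]],
                        "start": int(pos[run].min()) - 1,
                        "end": int(pos[run].max()),
                        "probe_ids": ";".join(assay["probe_id"].iloc[run]),
                        "L": len(run),
                        "area": float(np.abs(seg).sum()),
                        "value": float(seg.mean()),
                        "cluster": cid,
                    }
                )
        out = pd.DataFrame(
            rows,
            columns=["chromosome", "start", "end", "probe_ids", "L", "area",
                     "value", "cluster"],
        )
        return out.sort_values("area", ascending=False).reset_index(drop=True)


def find_bumps(
    effects: np.ndarray,
    manifest: pd.DataFrame,
    clusters: pd.Series,
    cutoff: float,
    smooth_span: int = 3,
) -> pd.DataFrame:
    """Candidate bumps from one vector of per-probe effects.

    Effects are smoothed within clusters; bumps are maximal runs of
    |smoothed| >= cutoff.  Coordinates are emitted 0-based half-open
    (manifest positions are 1-based).
    """
    eng = _BumpEngine(manifest, clusters, cutoff, smooth_span)
    eff = np.asarray(effects, dtype=np.float64)
    if len(eff) != len(eng.assay):
        raise StoreError("effects not aligned with manifest assay probes")
    return eng.bumps(eff)


def _effect_operator(X: np.ndarray, t_ix: int) -> np.ndarray:
    """Row of the OLS hat operator giving the target coefficient:
    effect vector = betas @ h."""
    return np.linalg.inv(X.T @ X)[t_ix] @ X.T


def bumphunt(
    source,
    design: pd.DataFrame,
    target: str,
    manifest: pd.DataFrame,
    covariates: list[str] | None = None,
    clusters: pd.Series | None = None,
    cutoff: float = 0.1,
    smooth_span: int = 3,
    max_gap: int = 500,
    n_perm: int = 100,
    seed: int = 0,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Bump hunting with permutation inference.

    Observed effects come from the probewise OLS target coefficient
    (probes with missing betas are mean-imputed so the same linear
    operator applies to every permutation).  The null permutes the
    target variable across samples, keeping covariates attached to
    their samples; p_value and fwer are the tail probability of the
    observed bump area under the per-permutation maximum null area.
    """
    X, t_ix = _design_matrix(design, target, covariates)
    if clusters is None:
        clusters = cluster_probes(manifest, max_gap)
    if isinstance(source, MethylStore):
        blocks = [blk for _, blk in source.iter_row_blocks("betas")]
        Y = np.vstack(blocks) if blocks else np.empty((0, source.n_samples))
    else:
        Y = np.asarray(source, dtype=np.float64)
    # mean-impute missing betas so effects are a fixed linear map of Y
    row_mean = np.nanmean(np.where(np.isnan(Y), np.nan, Y), axis=1, keepdims=True)
    row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
    Yf = np.where(np.isnan(Y), row_mean, Y)

    engine = _BumpEngine(manifest, clusters, cutoff, smooth_span)
    h = _effect_operator(X, t_ix)
    observed = Yf @ h
    bumps = engine.bumps(observed)
    if n_perm <= 0 or len(bumps) == 0:
        bumps["p_value"] = np.nan
        bumps["fwer"] = np.nan
        return bumps

    rng = np.random.default_rng(seed)
    tcol = design[target].to_numpy(dtype=np.float64)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(tcol))
        Xp = X.copy()
        Xp[:, t_ix] = tcol[perm]
        if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
            null_max[b] = 0.0
            continue
        null_max[b] = engine.max_area(Yf @ _effect_operator(Xp, t_ix))

    areas = bumps["area"].to_numpy()
    exceed = (null_max[None, :] >= areas[:, None]).sum(axis=1)
    pvals = (1 + exceed) / (n_perm + 1)
    bumps["p_value"] = pvals
    bumps["fwer"] = pvals
    return bumps


def write_bumps_bed(bumps: pd.DataFrame, path: str) -> str:
    """BED export: chrom, start, end, name, score = -10*log10(p)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, row in bumps.iterrows():
            p = row.get("p_value", np.nan)
            score = -10.0 * np.log10(p) if np.isfinite(p) and p > 0 else 0.0
            fh.write(
                f"{row['chromosome']}\t{row['start']}\t{row['end']}\t"
                f"bump{i + 1}\t{score:.2f}\n"
            )
    return path
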