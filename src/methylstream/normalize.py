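"""Bounded-memory two-pass quantile normalization.

Pass 1 streams sample columns and accumulates the elementwise mean of
the sorted columns — the reference quantile vector.  Pass 2 streams the
columns again and replaces each value by the reference value at its
within-column rank, ties receiving the mean of the tied reference
positions (the classic dense tie rule), so the chunked result matches
the in-memory algorithm exactly.

Columns with missing values are handled by interpolating their sorted
values onto the full-length quantile grid in pass 1 and by interpolating
the reference at the (mean) fractional rank in pass 2; NaNs stay NaN.

``dasen`` is the probe-type-stratified variant: methylated and
unmethylated intensities are quantile-normalized separately within each
Infinium design-type group (four groups), then betas are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .store import MethylStore, StoreError

__all__ = [
    "QuantileReference",
    "build_reference_quantiles",
    "apply_quantile_normalization",
    "quantile_normalize",
    "dasen",
    "design_type_groups",
]


@dataclass
class QuantileReference:
    """Per-group mean-quantile target distributions.

    ``vectors[g]`` is the non-decreasing reference vector for group ``g``
    (length = number of rows in the group); ``group_rows[g]`` holds the
    store row indices the group covers.
    """

    vectors: dict[str, np.ndarray]
    group_rows: dict[str, np.ndarray]
    n_samples: int
    nan_policy: str = "interpolate"
    array_name: str = field(default="")

    def __post_init__(self) -> None:
        for g, v in self.vectors.items():
            if np.any(np.diff(v[~np.isnan(v)]) < 0):
                raise StoreError(f"reference vector for group {g!r} not sorted")

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"group": g, "rank": np.arange(len(v)), "value": v})
            for g, v in self.vectors.items()
        ]
        return pd.concat(parts, ignore_index=True)


def design_type_groups(manifest: pd.DataFrame) -> dict[str, np.ndarray]:
    """Row-index groups by Infinium design type (assay probes, store order)."""
    assay = manifest[~manifest.get("is_control", False).astype(bool)].reset_index(
        drop=True
    )
    groups = {
        str(t): np.flatnonzero((assay["design_type"] == t).to_numpy())
        for t in sorted(assay["design_type"].dropna().unique())
    }
    return {g: ix for g, ix in groups.items() if len(ix)}


def _sorted_to_grid(sorted_valid: np.ndarray, length: int) -> np.ndarray:
    """Interpolate a sorted vector of v valid values onto a length-L
    quantile grid (identity when v == L)."""
    v = len(sorted_valid)
    if v == length:
        return sorted_valid
    if v == 1:
        return np.full(length, sorted_valid[0])
    src = np.linspace(0.0, 1.0, v)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, sorted_valid)


def build_reference_quantiles(
    store: MethylStore,
    array_name: str = "betas",
    groups: dict[str, np.ndarray] | None = None,
) -> QuantileReference:
    """Pass 1: stream columns, sort within groups, average the sorted
    vectors across samples."""
    P, S = store.n_probes, store.n_samples
    if S == 0:
        raise StoreError("store has no samples")
    if groups is None:
        groups = {"all": np.arange(P)}
    for g, ix in groups.items():
        if len(ix) < 2:
            raise StoreError(f"group {g!r} has fewer than 2 rows")
    sums = {g: np.zeros(len(ix)) for g, ix in groups.items()}
    for c0, block in store.iter_col_blocks(array_name):
        for g, ix in groups.items():
            sub = block[ix]
            for j in range(sub.shape[1]):
                col = sub[:, j]
                valid = col[~np.isnan(col)]
                if len(valid) == 0:
                    raise StoreError(
                        f"sample column {c0 + j} is all-NaN in group {g!r}"
                    )
                valid.sort()
                sums[g] += _sorted_to_grid(valid, len(ix))
    vectors = {g: s / S for g, s in sums.items()}
    return QuantileReference(
        vectors=vectors,
        group_rows={g: np.asarray(ix) for g, ix in groups.items()},
        n_samples=S,
        array_name=array_name,
    )


def _normalize_column(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map one group-restricted column onto the reference distribution.

    Full columns get the exact tie-mean rule: tied values receive the
    mean of the reference values at the tied sort positions.  Columns
    with NaNs map the mean fractional rank of the valid values onto the
    reference grid by interpolation; NaNs stay NaN.
    """
    out = np.full_like(values, np.nan)
    mask = ~np.isnan(values)
    valid = values[mask]
    v, L = len(valid), len(ref)
    if v == 0:
        return out
    order = np.argsort(valid, kind="stable")
    if v == L:
        assigned = np.empty(v)
        assigned[order] = ref
        # average assigned reference values within tie groups
        uniq, inv = np.unique(valid, return_inverse=True)
        sums = np.bincount(inv, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inv, minlength=len(uniq))
        out[mask] = (sums / counts)[inv]
        return out
    ranks = np.empty(v)
    ranks[order] = np.arange(v, dtype=float)
    uniq, inv = np.unique(valid, return_inverse=True)
    mean_rank = np.bincount(inv, weights=ranks) / np.bincount(inv)
    frac = mean_rank[inv] / (v - 1) if v > 1 else np.full(v, 0.5)
    out[mask] = np.interp(frac * (L - 1), np.arange(L), ref)
    return out


def apply_quantile_normalization(
    store: MethylStore,
    array_name: str,
    reference: QuantileReference,
    out_array_name: str,
) -> MethylStore:
    """Pass 2: stream columns and write the rank-mapped values to a new
    assay; rows outside every group are copied through unchanged."""
    P = store.n_probes
    covered = np.zeros(P, dtype=bool)
    for g, ix in reference.group_rows.items():
        if len(reference.vectors[g]) != len(ix):
            raise StoreError(f"reference length mismatch for group {g!r}")
        if len(ix) and ix.max() >= P:
            raise StoreError(f"group {g!r} indexes beyond store rows")
        covered[ix] = True
    store.add_array(out_array_name)
    for c0, block in store.iter_col_blocks(array_name):
        out = block.copy()
        for g, ix in reference.group_rows.items():
            ref = reference.vectors[g]
            sub = block[ix]
            for j in range(sub.shape[1]):
                out[ix, j] = _normalize_column(sub[:, j], ref)
        store.write_block(out_array_name, out, 0, c0)
    return store


def quantile_normalize(
    store: MethylStore,
    array_name: str = "betas",
    out_array_name: str = "betas_norm",
    groups: dict[str, np.ndarray] | None = None,
) -> QuantileReference:
    """Two-pass quantile normalization of one assay; returns the reference."""
    ref = build_reference_quantiles(store, array_name, groups)
    apply_quantile_normalization(store, array_name, ref, out_array_name)
    return ref


def dasen(
    store: MethylStore,
    manifest: pd.DataFrame | None = None,
    alpha: float = 100.0,
    out_array_name: str = "betas_norm",
) -> MethylStore:
    """Design-type-stratified quantile normalization of M and U, then
    beta recomputation — the dasen-style normalizer.

    M and U are normalized separately within each design-type group
    (2 arrays x 2 types = four groups); normalized intensities land in
    ``methylated_norm``/``unmethylated_norm`` and betas recomputed with
    offset ``alpha`` in ``out_array_name``.  Raw arrays are untouched.
    """
    manifest = store.probe_index if manifest is None else manifest
    groups = design_type_groups(manifest)
    if not groups:
        raise StoreError("manifest has no design types")
    for src, dst in (
        ("methylated", "methylated_norm"),
        ("unmethylated", "unmethylated_norm"),
    ):
        ref = build_reference_quantiles(store, src, groups)
        apply_quantile_normalization(store, src, ref, dst)
    store.add_array(out_array_name)
    P = store.n_probes
    for c0, m_block in store.iter_col_blocks("methylated_norm"):
        u_block = store.read_block(
            "unmethylated_norm", (0, P), (c0, c0 + m_block.shape[1])
        )
        with np.errstate(invalid="ignore"):
            denom = m_block + u_block + alpha
            betas = np.where(denom > 0, m_block / denom, 0.0)
            betas[np.isnan(m_block) | np.isnan(u_block)] = np.nan
        store.write_block(out_array_name, betas, 0, c0)
    return store
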