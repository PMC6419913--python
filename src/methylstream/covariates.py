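"""Covariate estimation from methylation: age, and cell composition.

Age comes from an epigenetic clock — a linear predictor over CpG betas
whose output passes through the piecewise log-linear age transform
F(age) = log(age+1) - log(adult_age+1) below ``adult_age`` and
(age - adult_age)/(adult_age+1) above it.  Clock coefficients are input
data (CSV), never vendored.

Cell composition uses reference-based deconvolution: each sample's beta
vector over a panel of discriminating probes is regressed onto the
reference cell-type profiles under non-negativity and a sum constraint
(Houseman-style constrained projection), solved by active-set
non-negative least squares on a penalty-augmented system.  Instead of
quantile-normalizing the reference together with the study data, the
study's mean quantiles can be imposed on the reference alone — with a
large study the reference's contribution to the joint quantiles is
negligible, so the two routes agree while the imposition never touches
the study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .normalize import QuantileReference, _normalize_column, _sorted_to_grid
from .store import MethylStore, StoreError

__all__ = [
    "ClockModel",
    "ReferencePanel",
    "transform_age",
    "anti_transform_age",
    "predict_age",
    "read_clock",
    "write_clock",
    "read_panel",
    "write_panel",
    "impose_quantiles_on_reference",
    "co_normalize_with_reference",
    "estimate_cell_counts",
]

_PENALTY = 1e6


@dataclass
class ClockModel:
    """Linear epigenetic clock: intercept + sum(coef * beta), optionally
    followed by the inverse age transform."""

    name: str
    intercept: float
    coefficients: pd.Series  # index: probe_id
    adult_age: float = 21.0
    transform: str = "horvath_log_linear"
    reference_means: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise StoreError("clock has no coefficients")
        if self.coefficients.index.duplicated().any():
            raise StoreError("duplicate probe id in clock")
        if self.transform not in ("horvath_log_linear", "identity"):
            raise StoreError(f"unknown transform {self.transform!r}")


def transform_age(age, adult_age: float = 21.0):
    """Forward age transform F(age); log-linear below adult_age, linear above."""
    age = np.asarray(age, dtype=np.float64)
    return np.where(
        age <= adult_age,
        np.log(age + 1) - np.log(adult_age + 1),
        (age - adult_age) / (adult_age + 1),
    )


def anti_transform_age(x, adult_age: float = 21.0):
    """Inverse of the age transform: continuous, strictly increasing,
    with fixed point age = adult_age at x = 0."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(
        x <= 0,
        (adult_age + 1) * np.exp(x) - 1,
        (adult_age + 1) * x + adult_age,
    )


def read_clock(csv_path: str) -> ClockModel:
    """Read a clock CSV: leading ``#key=value`` comment lines for name /
    intercept / adult_age / transform, then probe_id,coefficient rows
    (optional reference_mean column for imputation)."""
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(csv_path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                rows.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), dtype={"probe_id": str})
    coef = pd.Series(df["coefficient"].to_numpy(), index=df["probe_id"])
    ref = None
    if "reference_mean" in df.columns:
        ref = pd.Series(df["reference_mean"].to_numpy(), index=df["probe_id"])
    return ClockModel(
        name=meta.get("name", "clock"),
        intercept=float(meta.get("intercept", 0.0)),
        coefficients=coef,
        adult_age=float(meta.get("adult_age", 21.0)),
        transform=meta.get("transform", "horvath_log_linear"),
        reference_means=ref,
    )


def write_clock(clock: ClockModel, csv_path: str) -> None:
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write(f"#name={clock.name}\n#intercept={clock.intercept!r}\n")
        fh.write(f"#adult_age={clock.adult_age!r}\n#transform={clock.transform}\n")
        cols = "probe_id,coefficient"
        if clock.reference_means is not None:
            cols += ",reference_mean"
        fh.write(cols + "\n")
        for pid, c in clock.coefficients.items():
            line = f"{pid},{c!r}"
            if clock.reference_means is not None:
                line += f",{clock.reference_means[pid]!r}"
            fh.write(line + "\n")


def _betas_at_probes(source, probe_ids: pd.Index) -> pd.DataFrame:
    """Beta values at the requested probes as (probe x sample) frame;
    probes absent from the source are NaN rows."""
    if isinstance(source, MethylStore):
        store_probes = pd.Index(source.probe_ids)
        pos = store_probes.get_indexer(probe_ids)
        found = np.flatnonzero(pos >= 0)
        rows = np.sort(pos[found])
        block = source._dataset("betas")[rows, :] if len(rows) else np.empty((0, source.n_samples))
        from . import _memory

        _memory.track(block.size)
        df = pd.DataFrame(
            np.full((len(probe_ids), source.n_samples), np.nan),
            index=probe_ids,
            columns=source.sample_ids,
        )
        df.iloc[found] = pd.DataFrame(
            block, index=store_probes[rows], columns=source.sample_ids
        ).loc[probe_ids[found]].to_numpy()
        return df
    df = pd.DataFrame(source)
    return df.reindex(probe_ids)


def predict_age(
    source,
    clock: ClockModel,
    missing_policy: str = "drop",
    min_present: float = 0.8,
) -> pd.DataFrame:
    """Per-sample clock age: linear score over available clock probes,
    then the inverse age transform.

    ``missing_policy``: "drop" omits missing probes from the score;
    "impute_reference_mean" substitutes the clock's reference means.
    If fewer than ``min_present`` of the clock probes are present in the
    source at all, the prediction is refused.
    """
    betas = _betas_at_probes(source, clock.coefficients.index)
    present = ~betas.isna().all(axis=1)
    if present.mean() < min_present:
        raise StoreError(
            f"only {present.mean():.0%} of clock probes present "
            f"(needs >= {min_present:.0%})"
        )
    coef = clock.coefficients.to_numpy()[:, None]
    B = betas.to_numpy()
    missing = np.isnan(B)
    if missing_policy == "impute_reference_mean":
        if clock.reference_means is None:
            raise StoreError("clock carries no reference means to impute with")
        fill = clock.reference_means.reindex(clock.coefficients.index).to_numpy()
        B = np.where(missing, fill[:, None], B)
        missing = np.isnan(B)
    elif missing_policy != "drop":
        raise StoreError(f"unknown missing_policy {missing_policy!r}")
    score = clock.intercept + np.nansum(np.where(missing, 0.0, B) * coef, axis=0)
    age = (
        anti_transform_age(score, clock.adult_age)
        if clock.transform == "horvath_log_linear"
        else score
    )
    return pd.DataFrame(
        {
            "sample_id": list(betas.columns),
            "predicted_age": age,
            "n_missing": missing.sum(axis=0),
        }
    )


# -- cell composition --------------------------------------------------


@dataclass
class ReferencePanel:
    """Reference methylation profiles at discriminating probes.

    ``mean_betas`` is a (probe x cell-type) frame in [0, 1]; optional
    ``m``/``u`` intensity frames (same shape) enable quantile imposition;
    ``design_type`` per probe drives the imposition grouping.
    """

    mean_betas: pd.DataFrame
    m: pd.DataFrame | None = None
    u: pd.DataFrame | None = None
    design_type: pd.Series | None = field(default=None)

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_betas.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.mean_betas.index

    def __post_init__(self) -> None:
        vals = self.mean_betas.to_numpy(dtype=np.float64)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise StoreError("panel betas outside [0, 1]")
        if self.mean_betas.index.duplicated().any():
            raise StoreError("duplicate probe id in panel")


def read_panel(beta_csv: str, m_csv: str | None = None, u_csv: str | None = None,
               manifest: pd.DataFrame | None = None) -> ReferencePanel:
    beta = pd.read_csv(beta_csv, dtype={"probe_id": str}).set_index("probe_id")
    design = None
    if "design_type" in beta.columns:
        design = beta.pop("design_type")
    elif manifest is not None:
        design = manifest.set_index("probe_id")["design_type"].reindex(beta.index)
    m = u = None
    if m_csv:
        m = pd.read_csv(m_csv, dtype={"probe_id": str}).set_index("probe_id").reindex(beta.index)
    if u_csv:
        u = pd.read_csv(u_csv, dtype={"probe_id": str}).set_index("probe_id").reindex(beta.index)
    return ReferencePanel(mean_betas=beta, m=m, u=u, design_type=design)


def write_panel(panel: ReferencePanel, beta_csv: str, m_csv: str | None = None,
                u_csv: str | None = None) -> None:
    out = panel.mean_betas.copy()
    if panel.design_type is not None:
        out.insert(0, "design_type", panel.design_type)
    out.to_csv(beta_csv, index_label="probe_id")
    if m_csv and panel.m is not None:
        panel.m.to_csv(m_csv, index_label="probe_id")
    if u_csv and panel.u is not None:
        panel.u.to_csv(u_csv, index_label="probe_id")


def _panel_groups(panel: ReferencePanel) -> dict[str, np.ndarray]:
    if panel.design_type is None:
        return {"all": np.arange(len(panel.probe_ids))}
    groups = {}
    for t in sorted(panel.design_type.dropna().unique()):
        groups[str(t)] = np.flatnonzero((panel.design_type == t).to_numpy())
    return groups


def impose_quantiles_on_reference(
    panel: ReferencePanel,
    m_reference: QuantileReference,
    u_reference: QuantileReference,
    alpha: float = 100.0,
) -> ReferencePanel:
    """Quantile-map the panel's M and U columns onto the study's mean
    quantiles (per design-type group) and recompute the panel betas.
    The study data itself is untouched."""
    if panel.m is None or panel.u is None:
        raise StoreError("panel carries no M/U matrices; cannot impose quantiles")
    groups = _panel_groups(panel)
    new = {}
    for name, ref_q in (("m", m_reference), ("u", u_reference)):
        src = getattr(panel, name).to_numpy(dtype=np.float64)
        out = src.copy()
        for g, ix in groups.items():
            key = g if g in ref_q.vectors else "all"
            if key not in ref_q.vectors:
                raise StoreError(f"study reference lacks quantiles for group {g!r}")
            target = ref_q.vectors[key]
            for j in range(src.shape[1]):
                out[ix, j] = _normalize_column(src[ix, j], target)
        new[name] = pd.DataFrame(out, index=panel.probe_ids, columns=panel.cell_types)
    with np.errstate(invalid="ignore"):
        betas = new["m"].to_numpy() / (
            new["m"].to_numpy() + new["u"].to_numpy() + alpha
        )
    return ReferencePanel(
        mean_betas=pd.DataFrame(
            np.clip(betas, 0.0, 1.0), index=panel.probe_ids, columns=panel.cell_types
        ),
        m=new["m"],
        u=new["u"],
        design_type=panel.design_type,
    )


def co_normalize_with_reference(
    study_m: pd.DataFrame,
    study_u: pd.DataFrame,
    panel: ReferencePanel,
    alpha: float = 100.0,
) -> tuple[pd.DataFrame, ReferencePanel]:
    """Jointly quantile-normalize study and reference columns (the
    conventional route the imposition shortcut replaces); returns the
    normalized study betas at panel probes and the adjusted panel."""
    if panel.m is None or panel.u is None:
        raise StoreError("panel carries no M/U matrices")
    groups = _panel_groups(panel)
    n_study = study_m.shape[1]
    norm = {}
    for name, study, ref in (("m", study_m, panel.m), ("u", study_u, panel.u)):
        joint = np.concatenate(
            [study.reindex(panel.probe_ids).to_numpy(dtype=np.float64),
             ref.to_numpy(dtype=np.float64)],
            axis=1,
        )
        out = joint.copy()
        for g, ix in groups.items():
            sub = joint[ix]
            cols = []
            for j in range(sub.shape[1]):
                col = sub[:, j]
                valid = np.sort(col[~np.isnan(col)])
                cols.append(_sorted_to_grid(valid, len(ix)))
            target = np.mean(cols, axis=0)
            for j in range(sub.shape[1]):
                out[ix, j] = _normalize_column(sub[:, j], target)
        norm[name] = out
    with np.errstate(invalid="ignore"):
        betas = norm["m"] / (norm["m"] + norm["u"] + alpha)
    betas = np.clip(betas, 0.0, 1.0)
    study_betas = pd.DataFrame(
        betas[:, :n_study], index=panel.probe_ids, columns=study_m.columns
    )
    new_panel = ReferencePanel(
        mean_betas=pd.DataFrame(
            betas[:, n_study:], index=panel.probe_ids, columns=panel.cell_types
        ),
        m=pd.DataFrame(norm["m"][:, n_study:], index=panel.probe_ids,
                       columns=panel.cell_types),
        u=pd.DataFrame(norm["u"][:, n_study:], index=panel.probe_ids,
                       columns=panel.cell_types),
        design_type=panel.design_type,
    )
    return study_betas, new_panel


def estimate_cell_counts(
    source,
    panel: ReferencePanel,
    constraint: str = "inequality",
    min_present: float = 0.5,
) -> pd.DataFrame:
    """Per-sample cell-type fractions by constrained projection.

    Solves min_w ||beta_s - B w||^2 with w >= 0 and sum(w) <= 1
    (``constraint="inequality"``, the default) or sum(w) = 1
    (``"equality"``), via Lawson-Hanson NNLS on a penalty-augmented
    system (slack variable carries the inequality).  Returns fractions
    per cell type plus the residual norm of the fit.
    """
    B_full = panel.mean_betas.to_numpy(dtype=np.float64)
    if B_full.size == 0 or np.linalg.matrix_rank(np.nan_to_num(B_full)) < B_full.shape[1]:
        raise StoreError("singular or empty reference panel")
    if constraint not in ("inequality", "equality"):
        raise StoreError(f"unknown constraint {constraint!r}")
    betas = _betas_at_probes(source, panel.probe_ids)
    K = len(panel.cell_types)
    records = []
    for sample in betas.columns:
        y = betas[sample].to_numpy(dtype=np.float64)
        ok = ~np.isnan(y) & ~np.isnan(B_full).any(axis=1)
        if ok.mean() < min_present:
            records.append([np.nan] * K + [np.nan, int(ok.sum())])
            continue
        A, b = B_full[ok], y[ok]
        if constraint == "inequality":
            A_aug = np.zeros((A.shape[0] + 1, K + 1))
            A_aug[:-1, :K] = A
            A_aug[-1, :] = _PENALTY
            b_aug = np.concatenate([b, [_PENALTY]])
        else:
            A_aug = np.vstack([A, np.full((1, K), _PENALTY)])
            b_aug = np.concatenate([b, [_PENALTY]])
        w, _ = nnls(A_aug, b_aug)
        w = w[:K]
        resid = float(np.linalg.norm(A @ w - b))
        records.append(list(w) + [resid, int(ok.sum())])
    out = pd.DataFrame(
        records, columns=[*panel.cell_types, "residual", "n_probes"],
    )
    out.insert(0, "sample_id", list(betas.columns))
    return out
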