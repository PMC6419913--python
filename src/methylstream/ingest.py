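"""Parsing of manifests, sample sheets and signal-intensity exports.

Raw input is a pair of probe-major TSV matrices of methylated (M) and
unmethylated (U) intensities plus a long-format control-probe TSV — the
text stand-in for binary IDAT parsing, which is out of scope.  Import
streams sample columns into the store in bounded blocks, reordering
probe rows to the store's manifest order; beta values are computed
on-disk as beta = M / (M + U + alpha) with the conventional offset
alpha = 100 damping low-intensity probes.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .store import Batch, MethylStore, StoreError

__all__ = [
    "parse_manifest",
    "parse_sample_sheet",
    "parse_control_tsv",
    "import_signal_matrix",
    "compute_betas",
    "export_dense",
    "IngestError",
]

MANIFEST_COLUMNS = ("probe_id", "design_type", "channel", "chromosome", "position")
DESIGN_TYPES = ("I", "II")


class IngestError(ValueError):
    """Malformed input file or inconsistent import request."""


def parse_manifest(csv_path: str) -> pd.DataFrame:
    """Read and validate a probe manifest CSV.

    Required columns: probe_id, design_type (I/II), channel, chromosome,
    position; optional: is_control, control_category, role (for paired
    bisulfite-conversion controls).  Row order is preserved.
    """
    df = pd.read_csv(csv_path, dtype={"probe_id": str, "chromosome": str})
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise IngestError(f"manifest missing required column {col!r}")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise IngestError(f"duplicate probe_id in manifest: {dup.iloc[0]!r}")
    if "is_control" not in df.columns:
        df["is_control"] = False
    df["is_control"] = df["is_control"].fillna(False).astype(bool)
    if "control_category" not in df.columns:
        df["control_category"] = ""
    df["control_category"] = df["control_category"].fillna("")
    assay = ~df["is_control"]
    bad = df.loc[assay & ~df["design_type"].isin(DESIGN_TYPES)]
    if len(bad):
        row = bad.index[0]
        raise IngestError(
            f"unknown design_type {bad['design_type'].iloc[0]!r} at manifest row {row}"
        )
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad_pos = df.loc[assay & ~(pos >= 1)]
    if len(bad_pos):
        raise IngestError(
            f"non-positive or missing position at manifest row {bad_pos.index[0]}"
        )
    df["position"] = pos.fillna(0).astype(np.int64)
    return df


def parse_sample_sheet(csv_path: str) -> pd.DataFrame:
    """Read an Illumina-style sample sheet; lines before a ``[Data]``
    section header are skipped if present."""
    with open(csv_path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip().strip('"').lower().startswith("[data]"):
            start = i + 1
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[start:])), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise IngestError("sample sheet missing sample_id column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise IngestError(f"duplicate sample_id in sheet: {dup.iloc[0]!r}")
    if "reported_sex" not in df.columns:
        df["reported_sex"] = "unknown"
    df["reported_sex"] = df["reported_sex"].fillna("unknown")
    return df


def _read_signal_header(tsv_path: str) -> list[str]:
    with open(tsv_path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "probe_id":
        raise IngestError(f"{tsv_path}: first column must be probe_id")
    return header[1:]


def _read_signal_columns(tsv_path: str, sample_cols: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        tsv_path,
        sep="\t",
        usecols=["probe_id", *sample_cols],
        dtype={"probe_id": str},
        index_col="probe_id",
        float_precision="round_trip",
    )
    for col in sample_cols:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col][coerced.isna() & df[col].notna() &
                          (df[col].astype(str).str.lower() != "nan")]
            if len(bad):
                raise IngestError(
                    f"{tsv_path}: non-numeric value {bad.iloc[0]!r} in column {col!r}"
                )
            df[col] = coerced
    return df[list(sample_cols)]


def parse_control_tsv(tsv_path: str) -> pd.DataFrame:
    """Read a long-format control TSV (probe_id, sample_id, green, red)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"probe_id": str, "sample_id": str})
    for col in ("probe_id", "sample_id", "green", "red"):
        if col not in df.columns:
            raise IngestError(f"control TSV missing column {col!r}")
    return df


def _control_array(
    ctrl: pd.DataFrame, probe_ids: Sequence[str], sample_ids: Sequence[str]
) -> np.ndarray:
    """Pivot the long control table to a (C, B, 2) array (green, red)."""
    out = np.full((len(probe_ids), len(sample_ids), 2), np.nan)
    pidx = {p: i for i, p in enumerate(probe_ids)}
    sidx = {s: j for j, s in enumerate(sample_ids)}
    for _, row in ctrl.iterrows():
        i = pidx.get(str(row["probe_id"]))
        j = sidx.get(str(row["sample_id"]))
        if i is not None and j is not None:
            out[i, j, 0] = row["green"]
            out[i, j, 1] = row["red"]
    return out


def import_signal_matrix(
    m_tsv: str,
    u_tsv: str,
    store: MethylStore,
    control_tsv: str | None = None,
    sample_sheet: pd.DataFrame | str | None = None,
    detection_tsv: str | None = None,
    strict: bool = False,
) -> MethylStore:
    """Stream a signal-TSV pair (plus optional controls and detection
    p-values) into the store in bounded column blocks.

    Probe rows are reordered to the store's manifest order; assay probes
    absent from the TSVs are filled with NaN (counted in a warning)
    unless ``strict`` is set.
    """
    m_samples = _read_signal_header(m_tsv)
    u_samples = _read_signal_header(u_tsv)
    if m_samples != u_samples:
        raise IngestError(
            f"sample columns differ between M ({len(m_samples)}) and "
            f"U ({len(u_samples)}) files"
        )
    if detection_tsv is not None and _read_signal_header(detection_tsv) != m_samples:
        raise IngestError("detection-p sample columns differ from M/U files")

    if isinstance(sample_sheet, str):
        sample_sheet = parse_sample_sheet(sample_sheet)
    if sample_sheet is not None:
        known = set(sample_sheet["sample_id"].astype(str))
        missing = [s for s in m_samples if s not in known]
        if missing:
            raise IngestError(f"sample {missing[0]!r} absent from sample sheet")

    store_probes = store.probe_ids
    ctrl_df = parse_control_tsv(control_tsv) if control_tsv else None
    ctrl_ids = store.control_probes
    ctrl_ids = (
        ctrl_ids["probe_id"].astype(str).tolist() if len(ctrl_ids) else []
    )

    cols_per_batch = max(1, store.chunk_spec.cols_for_rows(len(store_probes)))
    n_filled = 0
    for b0 in range(0, len(m_samples), cols_per_batch):
        cols = m_samples[b0 : b0 + cols_per_batch]
        m_df = _read_signal_columns(m_tsv, cols)
        u_df = _read_signal_columns(u_tsv, cols)
        absent = [p for p in store_probes if p not in m_df.index]
        if absent:
            if strict:
                raise IngestError(
                    f"probe {absent[0]!r} absent from signal TSV (strict mode)"
                )
            n_filled += len(absent)
        m_block = m_df.reindex(store_probes).to_numpy(dtype=np.float64)
        u_block = u_df.reindex(store_probes).to_numpy(dtype=np.float64)
        det_block = None
        if detection_tsv is not None:
            det_block = (
                _read_signal_columns(detection_tsv, cols)
                .reindex(store_probes)
                .to_numpy(dtype=np.float64)
            )
        ctrl_block = None
        if ctrl_df is not None and ctrl_ids:
            ctrl_block = _control_array(
                ctrl_df[ctrl_df["sample_id"].isin(cols)], ctrl_ids, cols
            )
        meta = None
        if sample_sheet is not None:
            meta = (
                sample_sheet.set_index("sample_id").loc[cols].reset_index()
            )
        store.append_samples(
            Batch(
                sample_ids=list(cols),
                probe_ids=store_probes,
                methylated=m_block,
                unmethylated=u_block,
                detection_p=det_block,
                control=ctrl_block,
                control_probe_ids=ctrl_ids if ctrl_block is not None else None,
                sample_meta=meta,
            )
        )
    if n_filled:
        warnings.warn(
            f"{n_filled} probe cells absent from signal TSVs filled with NaN",
            stacklevel=2,
        )
    return store


def compute_betas(store: MethylStore, alpha: float = 100.0) -> int:
    """Populate the betas assay as M / (M + U + alpha), streamed in blocks.

    Negative intensities propagate NaN (per-cell) and are counted; the
    count of NaN beta cells is returned.
    """
    if alpha < 0:
        raise IngestError("alpha must be non-negative")
    n_nan = 0
    for c0, m_block in store.iter_col_blocks("methylated"):
        u_block = store.read_block(
            "unmethylated", (0, store.n_probes), (c0, c0 + m_block.shape[1])
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            neg = (m_block < 0) | (u_block < 0)
            denom = m_block + u_block + alpha
            betas = np.where(denom > 0, m_block / denom, 0.0)
            betas[neg | np.isnan(m_block) | np.isnan(u_block)] = np.nan
        n_nan += int(np.isnan(betas).sum())
        store.write_block("betas", betas, 0, c0)
    if n_nan:
        warnings.warn(f"{n_nan} beta cells set to NaN", stacklevel=2)
    return n_nan


def export_dense(
    store: MethylStore,
    array_name: str,
    out_path: str,
    row_range: tuple[int, int] | None = None,
) -> str:
    """Write an assay as a probe-major TSV (probe_id + one column per
    sample), streamed in row blocks; re-import reproduces it exactly."""
    if array_name not in ("methylated", "unmethylated", "betas", "detection_p") and (
        not store.has_array(array_name)
    ):
        raise IngestError(f"unknown array {array_name!r}")
    probes = store.probe_ids
    samples = store.sample_ids
    r0, r1 = row_range if row_range else (0, store.n_probes)
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(samples) + "\n" if samples else "probe_id\n")
        if r1 > r0 and samples:
            h = store.chunk_spec.rows_for_cols(max(1, len(samples)))
            for s0 in range(r0, r1, h):
                s1 = min(r1, s0 + h)
                block = store.read_block(array_name, (s0, s1), (0, len(samples)))
                df = pd.DataFrame(block, index=probes[s0:s1])
                df.to_csv(fh, sep="\t", header=False, float_format="%.17g")
        elif r1 > r0:
            for p in probes[r0:r1]:
                fh.write(f"{p}\n")
    return out_path
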