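"""Disk-backed, chunked, append-able methylation data container.

A :class:`MethylStore` keeps the methylated/unmethylated intensity
matrices, derived beta values and optional detection p-values of a
methylation-array experiment in a single chunked HDF5 file, probe-major
(P rows x S sample columns).  Samples can be appended batch by batch —
the incremental workflow — while probes are fixed at creation from the
manifest.  All dense access is streamed in blocks no larger than the
configured ``max_block_elements``, and every materialized block is
registered with :mod:`methylstream._memory` so the bound is testable.

HDF5 layout (format version 1)::

    /assays/{methylated,unmethylated,betas,detection_p}   float64 (P, S)
    /probes        scalar UTF-8 CSV of the assay-probe table
    /samples       scalar UTF-8 CSV of the sample table
    /controls/intensities   float64 (C, S, 2)  channels (green, red)
    /controls/probes        scalar UTF-8 CSV of the control-probe table
    /history       appendable UTF-8 JSON-lines log
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from io import StringIO
from typing import Callable, Sequence

import h5py
import numpy as np
import pandas as pd

from . import _memory

__all__ = [
    "ChunkSpec",
    "Batch",
    "MethylStore",
    "create_store",
    "open_store",
    "StoreError",
]

ASSAY_NAMES = ("methylated", "unmethylated", "betas", "detection_p")
FORMAT_VERSION = 1
_STR = h5py.string_dtype(encoding="utf-8")


class StoreError(ValueError):
    """Structural or precondition failure on a MethylStore."""


@dataclass(frozen=True)
class ChunkSpec:
    """Chunk geometry and the dense-block memory cap.

    ``max_block_elements`` bounds every in-memory dense block (default
    2**24 elements, ~128 MB of float64); the chunk rectangle must fit
    under it.
    """

    rows_per_chunk: int = 4096
    cols_per_chunk: int = 64
    max_block_elements: int = 2**24

    def __post_init__(self) -> None:
        if self.rows_per_chunk < 1 or self.cols_per_chunk < 1:
            raise StoreError("chunk dimensions must be positive")
        if self.max_block_elements < 1:
            raise StoreError("max_block_elements must be positive")
        if self.rows_per_chunk * self.cols_per_chunk > self.max_block_elements:
            raise StoreError(
                "rows_per_chunk * cols_per_chunk exceeds max_block_elements"
            )

    @property
    def col_block(self) -> int:
        """Column-block width for whole-probe-axis streaming of P rows."""
        return self.cols_per_chunk

    def cols_for_rows(self, n_rows: int) -> int:
        """Widest column block such that n_rows * width fits under the cap."""
        return max(1, self.max_block_elements // max(1, n_rows))

    def rows_for_cols(self, n_cols: int) -> int:
        """Tallest row block such that height * n_cols fits under the cap."""
        return max(1, self.max_block_elements // max(1, n_cols))


@dataclass
class Batch:
    """One importable batch of samples, aligned to a probe order.

    ``methylated``/``unmethylated`` are (n_probes, n_samples) arrays in
    ``probe_ids`` row order; ``control`` is (n_control_probes, n_samples, 2)
    with channels (green, red) in ``control_probe_ids`` order.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    methylated: np.ndarray
    unmethylated: np.ndarray
    detection_p: np.ndarray | None = None
    control: np.ndarray | None = None
    control_probe_ids: list[str] | None = None
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        n_p, n_s = len(self.probe_ids), len(self.sample_ids)
        for name in ("methylated", "unmethylated"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (n_p, n_s):
                raise StoreError(
                    f"{name} block has shape {arr.shape}, expected {(n_p, n_s)}"
                )
            setattr(self, name, arr)
        if self.detection_p is not None:
            self.detection_p = np.asarray(self.detection_p, dtype=np.float64)
            if self.detection_p.shape != (n_p, n_s):
                raise StoreError("detection_p block shape mismatch")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=np.float64)
            if self.control.ndim != 3 or self.control.shape[1:] != (n_s, 2):
                raise StoreError(
                    "control block must be (n_control_probes, n_samples, 2)"
                )
        if len(set(self.sample_ids)) != n_s:
            raise StoreError("duplicate sample id within batch")


def _write_table(group: h5py.File | h5py.Group, name: str, df: pd.DataFrame) -> None:
    if name in group:
        del group[name]
    group.create_dataset(name, data=df.to_csv(index=False), dtype=_STR)


def _read_table(group: h5py.File | h5py.Group, name: str) -> pd.DataFrame:
    raw = group[name][()]
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8")
    if raw.strip() == "" or "\n" not in raw.strip() and "," not in raw:
        return pd.DataFrame()
    return pd.read_csv(StringIO(raw), dtype={"probe_id": str, "sample_id": str})


class MethylStore:
    """Chunked on-disk container of methylation arrays plus metadata tables.

    Use :func:`create_store` / :func:`open_store` rather than the
    constructor.  The handle keeps the HDF5 file open; call :meth:`close`
    or use it as a context manager.
    """

    def __init__(self, path: str, f: h5py.File):
        self.path = str(path)
        self._f = f

    # -- lifecycle -----------------------------------------------------

    @classmethod
    def create(
        cls,
        path: str,
        manifest: pd.DataFrame,
        chunk_spec: ChunkSpec | None = None,
    ) -> "MethylStore":
        chunk_spec = chunk_spec or ChunkSpec()
        path = str(path)
        if os.path.exists(path):
            if not h5py.is_hdf5(path):
                raise StoreError(f"existing non-store file at {path}; refusing")
            raise StoreError(f"store already exists at {path}")
        if manifest is None or len(manifest) == 0:
            raise StoreError("manifest is empty")
        manifest = manifest.reset_index(drop=True).copy()
        if "probe_id" not in manifest.columns:
            raise StoreError("manifest lacks a probe_id column")
        dup = manifest["probe_id"][manifest["probe_id"].duplicated()]
        if len(dup):
            raise StoreError(f"duplicate probe id in manifest: {dup.iloc[0]!r}")
        if "is_control" not in manifest.columns:
            manifest["is_control"] = False
        assay = manifest[~manifest["is_control"].astype(bool)].reset_index(drop=True)
        controls = manifest[manifest["is_control"].astype(bool)].reset_index(drop=True)
        if len(assay) == 0:
            raise StoreError("manifest contains no assay probes")

        f = h5py.File(path, "w")
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["rows_per_chunk"] = chunk_spec.rows_per_chunk
        f.attrs["cols_per_chunk"] = chunk_spec.cols_per_chunk
        f.attrs["max_block_elements"] = chunk_spec.max_block_elements
        P = len(assay)
        assays = f.create_group("assays")
        chunks = (min(chunk_spec.rows_per_chunk, P), chunk_spec.cols_per_chunk)
        for name in ASSAY_NAMES:
            assays.create_dataset(
                name,
                shape=(P, 0),
                maxshape=(P, None),
                chunks=chunks,
                dtype=np.float64,
                fillvalue=np.nan,
            )
        _write_table(f, "probes", assay)
        _write_table(
            f,
            "samples",
            pd.DataFrame({"sample_id": pd.Series([], dtype=str)}),
        )
        cgrp = f.create_group("controls")
        _write_table(cgrp, "probes", controls)
        C = len(controls)
        cgrp.create_dataset(
            "intensities",
            shape=(C, 0, 2),
            maxshape=(C, None, 2),
            chunks=(max(1, C), chunk_spec.cols_per_chunk, 2) if C else None,
            dtype=np.float64,
            fillvalue=np.nan,
        )
        f.create_dataset("history", shape=(0,), maxshape=(None,), dtype=_STR)
        f.flush()
        return cls(path, f)

    @classmethod
    def open(cls, path: str, mode: str = "r+") -> "MethylStore":
        path = str(path)
        if not os.path.exists(path):
            raise StoreError(f"no store at {path}")
        if not h5py.is_hdf5(path):
            raise StoreError(f"{path} is not a MethylStore container")
        f = h5py.File(path, mode)
        if "assays" not in f or "probes" not in f:
            f.close()
            raise StoreError(f"{path} is not a MethylStore container")
        return cls(path, f)

    def close(self) -> None:
        self._f.close()

    def __enter__(self) -> "MethylStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- basic properties ----------------------------------------------

    @property
    def chunk_spec(self) -> ChunkSpec:
        a = self._f.attrs
        return ChunkSpec(
            int(a["rows_per_chunk"]),
            int(a["cols_per_chunk"]),
            int(a["max_block_elements"]),
        )

    @property
    def n_probes(self) -> int:
        return self._f["assays/methylated"].shape[0]

    @property
    def n_samples(self) -> int:
        return self._f["assays/methylated"].shape[1]

    @property
    def probe_index(self) -> pd.DataFrame:
        return _read_table(self._f, "probes")

    @property
    def probe_ids(self) -> list[str]:
        return self.probe_index["probe_id"].astype(str).tolist()

    @property
    def sample_index(self) -> pd.DataFrame:
        df = _read_table(self._f, "samples")
        if "sample_id" not in df.columns:
            return pd.DataFrame({"sample_id": pd.Series([], dtype=str)})
        return df

    @property
    def sample_ids(self) -> list[str]:
        return self.sample_index["sample_id"].astype(str).tolist()

    @property
    def control_probes(self) -> pd.DataFrame:
        return _read_table(self._f["controls"], "probes")

    @property
    def control_block(self) -> np.ndarray:
        arr = self._f["controls/intensities"][()]
        _memory.track(arr.size)
        return arr

    @property
    def history(self) -> list[dict]:
        return [json.loads(s) for s in self._f["history"].asstr()[()]]

    def _log(self, event: str, **fields) -> None:
        entry = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event}
        entry.update(fields)
        ds = self._f["history"]
        ds.resize((ds.shape[0] + 1,))
        ds[-1] = json.dumps(entry)

    def has_array(self, name: str) -> bool:
        return name in self._f["assays"] and self._f[f"assays/{name}"].shape[1] > 0

    def populated(self, name: str) -> bool:
        """True if the named assay holds any non-NaN data (cheap heuristic:
        array written at least once)."""
        return bool(self._f["assays"].attrs.get(f"{name}_populated", False))

    def _mark_populated(self, name: str, value: bool = True) -> None:
        self._f["assays"].attrs[f"{name}_populated"] = value

    # -- append / remove -----------------------------------------------

    def append_samples(self, batch: Batch) -> "MethylStore":
        """Append a batch of samples, streamed in column blocks under the cap.

        The batch probe order must match the store exactly; batch sample
        ids must be disjoint from those already stored.
        """
        spec = self.chunk_spec
        store_probes = self.probe_ids
        if list(batch.probe_ids) != store_probes:
            bset = batch.probe_ids
            n = min(len(bset), len(store_probes))
            for i in range(n):
                if bset[i] != store_probes[i]:
                    raise StoreError(
                        f"probe-order mismatch at row {i}: batch has "
                        f"{bset[i]!r}, store has {store_probes[i]!r}"
                    )
            raise StoreError(
                f"probe count mismatch: batch {len(bset)}, store {len(store_probes)}"
            )
        existing = set(self.sample_ids)
        for sid in batch.sample_ids:
            if sid in existing:
                raise StoreError(f"duplicate sample id: {sid!r}")

        P, S0 = self.n_probes, self.n_samples
        B = len(batch.sample_ids)
        col_block = min(spec.cols_for_rows(P), spec.col_block)

        for name, data in (
            ("methylated", batch.methylated),
            ("unmethylated", batch.unmethylated),
            ("detection_p", batch.detection_p),
        ):
            ds = self._f[f"assays/{name}"]
            ds.resize((P, S0 + B))
            if data is None:
                continue
            for j0 in range(0, B, col_block):
                j1 = min(B, j0 + col_block)
                block = np.ascontiguousarray(data[:, j0:j1], dtype=np.float64)
                _memory.track(block.size)
                ds[:, S0 + j0 : S0 + j1] = block
            self._mark_populated(name)
        self._f["assays/betas"].resize((P, S0 + B))

        cds = self._f["controls/intensities"]
        C = cds.shape[0]
        cds.resize((C, S0 + B, 2))
        if batch.control is not None:
            if C == 0:
                raise StoreError("store has no control probes; cannot add control block")
            ctrl = batch.control
            if batch.control_probe_ids is not None:
                want = self.control_probes["probe_id"].astype(str).tolist()
                got = [str(p) for p in batch.control_probe_ids]
                if got != want:
                    order = {p: i for i, p in enumerate(got)}
                    missing = [p for p in want if p not in order]
                    if missing:
                        raise StoreError(f"control probe {missing[0]!r} absent from batch")
                    ctrl = ctrl[[order[p] for p in want]]
            if ctrl.shape[0] != C:
                raise StoreError("control block row count mismatch")
            _memory.track(ctrl.size)
            cds[:, S0 : S0 + B, :] = ctrl

        meta = batch.sample_meta
        if meta is None:
            meta = pd.DataFrame({"sample_id": batch.sample_ids})
        else:
            meta = meta.copy()
            if "sample_id" not in meta.columns:
                meta.insert(0, "sample_id", batch.sample_ids)
            else:
                meta = (
                    meta.set_index("sample_id")
                    .loc[batch.sample_ids]
                    .reset_index()
                )
        samples = self.sample_index
        samples = pd.concat([samples, meta], ignore_index=True) if len(samples) else meta
        _write_table(self._f, "samples", samples)
        self._log("append", n=B, source="batch", sample_ids_head=batch.sample_ids[:3])
        self._f.flush()
        return self

    def remove_samples(self, sample_ids: Sequence[str]) -> "MethylStore":
        """Drop the named sample columns from every array and the controls."""
        current = self.sample_ids
        pos = {s: i for i, s in enumerate(current)}
        for sid in sample_ids:
            if sid not in pos:
                raise StoreError(f"unknown sample id: {sid!r}")
        drop = {pos[s] for s in sample_ids}
        keep = [i for i in range(len(current)) if i not in drop]
        P = self.n_probes
        spec = self.chunk_spec
        keep_arr = np.asarray(keep, dtype=int)
        for name in ASSAY_NAMES:
            ds = self._f[f"assays/{name}"]
            row_block = spec.rows_for_cols(max(1, len(current)))
            # compact surviving columns in row-block strips, then shrink
            for r0 in range(0, P, row_block):
                r1 = min(P, r0 + row_block)
                strip = ds[r0:r1, :]
                _memory.track(strip.size)
                ds[r0:r1, : len(keep)] = strip[:, keep_arr] if len(keep) else strip[:, :0]
            ds.resize((P, len(keep)))
        cds = self._f["controls/intensities"]
        if cds.shape[0]:
            ctrl = cds[()]
            _memory.track(ctrl.size)
            cds.resize((cds.shape[0], len(keep), 2))
            if len(keep):
                cds[:, :, :] = ctrl[:, keep_arr, :]
        else:
            cds.resize((0, len(keep), 2))
        samples = self.sample_index.iloc[keep_arr].reset_index(drop=True) if len(keep) else (
            pd.DataFrame({"sample_id": pd.Series([], dtype=str)})
        )
        _write_table(self._f, "samples", samples)
        self._log("remove", n=len(drop), sample_ids=sorted(sample_ids))
        self._f.flush()
        return self

    # -- block access ---------------------------------------------------

    def _dataset(self, array_name: str) -> h5py.Dataset:
        if array_name not in self._f["assays"]:
            raise StoreError(f"unknown array: {array_name!r}")
        return self._f[f"assays/{array_name}"]

    def read_block(
        self,
        array_name: str,
        row_slice: slice | tuple[int, int] | None = None,
        col_slice: slice | tuple[int, int] | None = None,
        override_cap: bool = False,
    ) -> np.ndarray:
        """Read a dense block. Raises if the block exceeds the cap unless
        ``override_cap`` is set."""
        ds = self._dataset(array_name)
        P, S = ds.shape

        def _norm(sl, limit, axis):
            if sl is None:
                return 0, limit
            if isinstance(sl, slice):
                start = 0 if sl.start is None else sl.start
                stop = limit if sl.stop is None else sl.stop
            else:
                start, stop = sl
            if start < 0 or stop > limit or start > stop:
                raise StoreError(
                    f"{axis} slice [{start}:{stop}) out of bounds for size {limit}"
                )
            return start, stop

        r0, r1 = _norm(row_slice, P, "row")
        c0, c1 = _norm(col_slice, S, "column")
        n = (r1 - r0) * (c1 - c0)
        cap = self.chunk_spec.max_block_elements
        if n > cap and not override_cap:
            raise StoreError(
                f"requested block of {n} elements exceeds max_block_elements={cap}; "
                "pass override_cap=True to force"
            )
        _memory.track(n)
        return ds[r0:r1, c0:c1]

    def write_block(
        self,
        array_name: str,
        block: np.ndarray,
        row_start: int = 0,
        col_start: int = 0,
    ) -> None:
        """Write a dense block into an assay (used by normalization etc.)."""
        ds = self._dataset(array_name)
        block = np.asarray(block, dtype=np.float64)
        _memory.track(block.size)
        ds[
            row_start : row_start + block.shape[0],
            col_start : col_start + block.shape[1],
        ] = block
        self._mark_populated(array_name)

    def add_array(self, array_name: str) -> None:
        """Allocate an extra named (P, S) assay (e.g. normalized output)."""
        if array_name in self._f["assays"]:
            return
        spec = self.chunk_spec
        P, S = self.n_probes, self.n_samples
        self._f["assays"].create_dataset(
            array_name,
            shape=(P, S),
            maxshape=(P, None),
            chunks=(min(spec.rows_per_chunk, P), spec.cols_per_chunk),
            dtype=np.float64,
            fillvalue=np.nan,
        )

    def iter_col_blocks(self, array_name: str, cols_per_block: int | None = None):
        """Yield (col_start, block) over all samples, whole probe axis."""
        spec = self.chunk_spec
        P, S = self.n_probes, self.n_samples
        w = cols_per_block or min(spec.cols_for_rows(P), spec.col_block)
        for c0 in range(0, S, w):
            c1 = min(S, c0 + w)
            yield c0, self.read_block(array_name, (0, P), (c0, c1))

    def iter_row_blocks(self, array_name: str, rows_per_block: int | None = None):
        """Yield (row_start, block) over all probes, whole sample axis."""
        spec = self.chunk_spec
        P, S = self.n_probes, self.n_samples
        h = rows_per_block or min(spec.rows_for_cols(max(1, S)), spec.rows_per_chunk)
        for r0 in range(0, P, h):
            r1 = min(P, r0 + h)
            yield r0, self.read_block(array_name, (r0, r1), (0, S))

    def apply_rows(
        self,
        array_name: str,
        fn: Callable[[np.ndarray], np.ndarray | float],
        rows_per_block: int | None = None,
        n_workers: int = 1,
    ) -> np.ndarray:
        """Apply a pure per-row function over an assay in bounded blocks.

        ``fn`` maps one row (length-S vector) to a fixed-width numeric
        record; the result is a (P, width) array whose row i equals
        ``fn(row_i)`` regardless of block size or worker count.
        """
        spec = self.chunk_spec
        P, S = self.n_probes, self.n_samples
        if rows_per_block is not None and rows_per_block * max(1, S) > spec.max_block_elements:
            raise StoreError("rows_per_block * n_samples exceeds max_block_elements")

        out: np.ndarray | None = None
        width: int | None = None

        def run_rows(block: np.ndarray) -> list[np.ndarray]:
            return [np.atleast_1d(np.asarray(fn(block[i]), dtype=np.float64))
                    for i in range(block.shape[0])]

        for r0, block in self.iter_row_blocks(array_name, rows_per_block):
            if n_workers > 1 and block.shape[0] > 1:
                from concurrent.futures import ThreadPoolExecutor

                splits = np.array_split(np.arange(block.shape[0]), n_workers)
                with ThreadPoolExecutor(max_workers=n_workers) as ex:
                    parts = list(ex.map(lambda ix: run_rows(block[ix]), splits))
                records = [rec for part in parts for rec in part]
            else:
                records = run_rows(block)
            for i, rec in enumerate(records):
                if width is None:
                    width = rec.shape[0]
                    out = np.empty((P, width), dtype=np.float64)
                if rec.shape[0] != width:
                    raise StoreError(
                        f"fn returned width {rec.shape[0]} at row {r0 + i}, "
                        f"expected {width}"
                    )
                out[r0 + i] = rec
        if out is None:
            return np.empty((P, 0))
        return out


def create_store(
    path: str, manifest: pd.DataFrame, chunk_spec: ChunkSpec | None = None
) -> MethylStore:
    """Create an empty store at ``path`` from a probe manifest."""
    return MethylStore.create(path, manifest, chunk_spec)


def open_store(path: str, mode: str = "r+") -> MethylStore:
    """Open an existing store."""
    return MethylStore.open(path, mode)
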