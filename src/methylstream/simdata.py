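"""Seeded generator of EPIC-like synthetic methylation datasets.

Emits everything the pipeline ingests — manifest, sample sheet, M/U
signal TSVs, long-format control TSV — plus a machine-readable truth
record (ages, sexes, cell fractions, planted outliers, conversion
levels, DMRs) so every behavior of the toolkit can be tested against a
known answer.

The intensity model is deliberately simple: per-probe base betas come
from a three-mode Beta mixture (hypo / hemi / hyper-methylated), total
signal T is lognormal with a design-type-specific scale, and the pair
(M, U) = (beta*T, (1-beta)*T - alpha) is emitted so that the standard
beta recomputation M/(M+U+alpha) returns the planted beta exactly when
noise is off.  Planted structure: sex clusters on chrX probes, a toy
linear clock whose probes encode the transformed age exactly, cell-type
mixture probes that are exact panel mixtures, per-sample conversion
levels on control probes, outlier shifts, and spiked DMRs.

A single integer seed is expanded through a SeedSequence spawn tree so
sub-generators are independent and the output is reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import ClockModel, ReferencePanel, transform_age
from .store import Batch

__all__ = [
    "GENERATOR_VERSION",
    "SimTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_controls",
    "spike_bumps",
    "make_toy_clock",
]

GENERATOR_VERSION = "1"
ALPHA = 100.0
_FLOAT_FMT = "%.10g"


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset (JSON-serializable)."""

    seed: int
    ages: list[float]
    sexes: list[str]
    cell_fractions: list[list[float]]
    cell_types: list[str]
    outlier_flags: list[bool]
    conversion_levels: list[float]
    clock_probes: list[str]
    cellmix_probes: list[str]
    sex_probes: list[str]
    dmrs: list[dict] = field(default_factory=list)
    generator_version: str = GENERATOR_VERSION

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    """In-memory simulated dataset plus its planted truth.

    ``betas`` is the planted truth beta matrix; ``m``/``u`` are the
    emitted intensities (probe-major frames); ``control`` is the
    long-format control table.
    """

    manifest: pd.DataFrame
    sample_sheet: pd.DataFrame
    betas: pd.DataFrame
    m: pd.DataFrame
    u: pd.DataFrame
    control: pd.DataFrame
    truth: SimTruth
    clock: ClockModel | None = None
    panel: ReferencePanel | None = None
    total: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)

    def as_batch(self, sample_ids: list[str] | None = None) -> Batch:
        """Package (a subset of) the samples as a store-appendable batch."""
        cols = sample_ids or self.sample_ids
        ctrl_probes = self.manifest.loc[
            self.manifest["is_control"], "probe_id"
        ].tolist()
        ctrl = np.full((len(ctrl_probes), len(cols), 2), np.nan)
        pidx = {p: i for i, p in enumerate(ctrl_probes)}
        sidx = {s: j for j, s in enumerate(cols)}
        for _, row in self.control.iterrows():
            i, j = pidx.get(row["probe_id"]), sidx.get(row["sample_id"])
            if i is not None and j is not None:
                ctrl[i, j] = (row["green"], row["red"])
        sheet = self.sample_sheet.set_index("sample_id").loc[cols].reset_index()
        assay = self.manifest.loc[~self.manifest["is_control"], "probe_id"].tolist()
        return Batch(
            sample_ids=list(cols),
            probe_ids=assay,
            methylated=self.m.loc[assay, cols].to_numpy(),
            unmethylated=self.u.loc[assay, cols].to_numpy(),
            control=ctrl if ctrl_probes else None,
            control_probe_ids=ctrl_probes or None,
            sample_meta=sheet,
        )

    def write(self, out_dir: str) -> dict[str, str]:
        """Emit the ingest-dialect files; returns the path map."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "manifest": os.path.join(out_dir, "manifest.csv"),
            "sample_sheet": os.path.join(out_dir, "samples.csv"),
            "m": os.path.join(out_dir, "methylated.tsv"),
            "u": os.path.join(out_dir, "unmethylated.tsv"),
            "control": os.path.join(out_dir, "controls.tsv"),
            "truth": os.path.join(out_dir, "truth.json"),
        }
        self.manifest.to_csv(paths["manifest"], index=False)
        self.sample_sheet.to_csv(paths["sample_sheet"], index=False)
        self.m.to_csv(paths["m"], sep="\t", index_label="probe_id",
                      float_format=_FLOAT_FMT)
        self.u.to_csv(paths["u"], sep="\t", index_label="probe_id",
                      float_format=_FLOAT_FMT)
        self.control.to_csv(paths["control"], sep="\t", index=False,
                            float_format=_FLOAT_FMT)
        self.truth.to_json(paths["truth"])
        return paths


def _positions(P: int, rng: np.random.Generator, n_sex: int):
    """Probe coordinates: runs of 1-12 probes spaced 100 bp apart inside
    a cluster, 5 kb between clusters, spread over chr1-chr5; the last
    ``n_sex`` probes land on chrX with the same geometry."""
    chroms, pos = [], []
    cluster_sizes = [1, 2, 3, 5, 8, 12]
    autosomes = [f"chr{i}" for i in range(1, 6)]
    n_auto = P - n_sex
    ci, cursor, chrom_i = 0, 1000, 0
    per_chrom = max(1, n_auto // len(autosomes))
    for start in range(0, n_auto, 1):
        if len(pos) and len(pos) % per_chrom == 0 and chrom_i < len(autosomes) - 1:
            chrom_i += 1
            cursor = 1000
        size = cluster_sizes[ci % len(cluster_sizes)]
        run = min(size, n_auto - len(pos))
        for k in range(run):
            chroms.append(autosomes[chrom_i])
            pos.append(cursor)
            cursor += 100
        cursor += 5000
        ci += 1
        if len(pos) >= n_auto:
            break
    cursor = 1000
    for k in range(n_sex):
        chroms.append("chrX")
        pos.append(cursor)
        cursor += 100 if (k % 6) else 5100
    return chroms[:P], pos[:P]


def make_toy_clock(
    probe_ids: list[str],
    base_betas: np.ndarray,
    rng: np.random.Generator,
    adult_age: float = 21.0,
    name: str = "toy-clock",
) -> tuple[ClockModel, np.ndarray, float]:
    """A synthetic linear clock over the given probes.

    Returns (clock, gamma, mean_score): sample betas built as
    base + gamma * (F(age) - mean_score) score exactly to F(age).
    """
    n = len(probe_ids)
    coef = rng.uniform(0.5, 1.5, n) * rng.choice([-1.0, 1.0], n)
    gamma = coef / (coef @ coef)
    mean_score = 0.0
    intercept = mean_score - float(coef @ base_betas)
    clock = ClockModel(
        name=name,
        intercept=intercept,
        coefficients=pd.Series(coef, index=pd.Index(probe_ids, name="probe_id")),
        adult_age=adult_age,
        transform="horvath_log_linear",
        reference_means=pd.Series(base_betas, index=probe_ids),
    )
    return clock, gamma, mean_score


def _emit_intensities(
    betas: np.ndarray,
    design_type: np.ndarray,
    rng: np.random.Generator,
    intensity_noise_sd: float,
    alpha: float = ALPHA,
):
    """(M, U, T) such that M/(M+U+alpha) reproduces beta exactly
    (up to U clipping at zero for near-1 betas)."""
    base_t = np.where(design_type == "I", 6000.0, 5000.0)[:, None]
    if intensity_noise_sd > 0:
        t = base_t * np.exp(
            rng.normal(0.0, intensity_noise_sd, size=betas.shape)
        )
    else:
        t = np.broadcast_to(base_t, betas.shape).copy()
    m = betas * t
    u = np.maximum((1.0 - betas) * t - alpha, 0.0)
    return m, u, t


def simulate_controls(
    S: int,
    conversion_level: float | np.ndarray = 0.98,
    noise_sd: float = 0.01,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    n_pairs_type1: int = 3,
    n_type2: int = 4,
    base_intensity: float = 3000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bisulfite-conversion control probes at a tunable conversion level.

    Returns (control manifest rows, long-format intensity table).  The
    expected bscon readout is 100 * conversion_level; multiplicative
    lognormal noise of scale ``noise_sd`` perturbs each intensity.
    """
    level = np.asarray(conversion_level, dtype=np.float64)
    if level.ndim == 0:
        level = np.full(S, float(level))
    if np.any((level < 0) | (level > 1)):
        raise ValueError("conversion_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sample_ids = sample_ids or [f"S{j + 1:03d}" for j in range(S)]

    rows_manifest = []
    for ch in ("Grn", "Red"):
        for i in range(n_pairs_type1):
            for role in ("converted", "unconverted"):
                rows_manifest.append(
                    {
                        "probe_id": f"BSC1_{ch}_{role[0].upper()}{i + 1}",
                        "design_type": "I",
                        "channel": ch,
                        "chromosome": "",
                        "position": 0,
                        "is_control": True,
                        "control_category": "BISULFITE CONVERSION I",
                        "role": role,
                    }
                )
    for i in range(n_type2):
        rows_manifest.append(
            {
                "probe_id": f"BSC2_{i + 1}",
                "design_type": "II",
                "channel": "Both",
                "chromosome": "",
                "position": 0,
                "is_control": True,
                "control_category": "BISULFITE CONVERSION II",
                "role": "",
            }
        )
    ctrl_manifest = pd.DataFrame(rows_manifest)

    def _noisy(x):
        if noise_sd > 0:
            return x * np.exp(rng.normal(0.0, noise_sd, size=np.shape(x)))
        return x

    records = []
    background = 100.0
    for _, probe in ctrl_manifest.iterrows():
        conv = _noisy(base_intensity * level)
        unconv = _noisy(base_intensity * (1.0 - level))
        if probe["control_category"] == "BISULFITE CONVERSION II":
            green, red = unconv, conv
        else:
            signal = conv if probe["role"] == "converted" else unconv
            if probe["channel"] == "Grn":
                green, red = signal, np.full(S, background)
            else:
                green, red = np.full(S, background), signal
        for j, sid in enumerate(sample_ids):
            records.append(
                {
                    "probe_id": probe["probe_id"],
                    "sample_id": sid,
                    "green": float(np.atleast_1d(green)[j]),
                    "red": float(np.atleast_1d(red)[j]),
                }
            )
    return ctrl_manifest, pd.DataFrame(records)


def simulate_dataset(
    P: int = 2000,
    S: int = 60,
    type1_fraction: float = 0.2,
    n_clock_probes: int = 50,
    cell_types: tuple[str, ...] = ("CD4T", "CD8T", "B", "NK", "Mono", "Gran"),
    n_cellmix_probes: int = 60,
    n_sex_probes: int = 40,
    n_outliers: int = 0,
    outlier_shift_sd: float = 10.0,
    outlier_probe_frac: float = 0.3,
    conversion_level: float | np.ndarray = 0.98,
    conversion_noise_sd: float = 0.01,
    beta_noise_sd: float = 0.015,
    intensity_noise_sd: float = 0.2,
    dmr_spec: list[dict] | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate an EPIC-like cohort with planted truth.

    Probe-wise base betas follow a hypo/hemi/hyper Beta mixture; planted
    structure (clock, sex clusters, cell mixtures, outliers, conversion
    levels, optional DMRs via ``dmr_spec`` entries like
    ``{"n_probes": 8, "delta": 0.3}``) is recorded in the truth object.
    """
    if P < 1 or S < 1:
        raise ValueError("P and S must be >= 1")
    n_sex_probes = min(n_sex_probes, max(0, P - 2))
    n_clock_probes = min(n_clock_probes, max(0, P - n_sex_probes) // 2)
    n_cellmix_probes = min(
        n_cellmix_probes, max(0, P - n_sex_probes - n_clock_probes)
    )
    seeds = np.random.SeedSequence(seed).spawn(8)
    rng_probe = np.random.default_rng(seeds[0])
    rng_sample = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])
    rng_clock = np.random.default_rng(seeds[3])
    rng_cell = np.random.default_rng(seeds[4])
    rng_out = np.random.default_rng(seeds[5])
    rng_int = np.random.default_rng(seeds[6])

    probe_ids = [f"cg{i + 1:07d}" for i in range(P)]
    chroms, pos = _positions(P, rng_probe, n_sex_probes)
    design_type = np.where(rng_probe.random(P) < type1_fraction, "I", "II")
    channel = np.where(design_type == "I",
                       np.where(rng_probe.random(P) < 0.5, "Grn", "Red"), "Both")

    # base betas: three-mode mixture, clipped away from the boundaries so
    # exact intensity emission stays invertible
    mode = rng_probe.choice(3, size=P, p=[0.45, 0.15, 0.40])
    a = np.choose(mode, [1.5, 5.0, 8.0])
    b = np.choose(mode, [8.0, 5.0, 1.5])
    base = np.clip(rng_probe.beta(a, b), 0.03, 0.95)

    sample_ids = [f"S{j + 1:03d}" for j in range(S)]
    ages = rng_sample.uniform(5.0, 75.0, S).round(2)
    sexes = np.array(["F" if j % 2 else "M" for j in range(S)])
    batch = np.array([f"batch{1 + (j // max(1, S // 2))}" for j in range(S)])
    # balanced two-group phenotype, shuffled so it is unconfounded with
    # sex, age and batch
    group = rng_sample.permutation(np.tile([0, 1], (S + 1) // 2)[:S])

    betas = np.tile(base[:, None], (1, S))

    # reserve whole clusters for planted DMRs before assigning the other
    # special probe sets, so each DMR occupies a clean positional run
    dmr_regions: list[tuple[list[int], float]] = []
    reserved_dmr: set[int] = set()
    if dmr_spec:
        chrom_arr = np.array(chroms)
        cluster_rows: list[list[int]] = []
        for i in range(P):
            if (
                cluster_rows
                and chrom_arr[i] == chrom_arr[cluster_rows[-1][-1]]
                and pos[i] - pos[cluster_rows[-1][-1]] <= 500
            ):
                cluster_rows[-1].append(i)
            else:
                cluster_rows.append([i])
        for spec in dmr_spec:
            want = int(spec["n_probes"])
            found = None
            for rows in cluster_rows:
                if len(rows) >= want and not (set(rows) & reserved_dmr) and (
                    chrom_arr[rows[0]] != "chrX"
                ):
                    found = rows[:want]
                    break
            if found is None:
                raise ValueError(
                    f"no free cluster with {want} probes for DMR spec {spec}"
                )
            reserved_dmr.update(rows)
            dmr_regions.append((found, float(spec["delta"])))
        # DMR probes keep headroom for the planted shift so clipping does
        # not erode the region signal
        if reserved_dmr:
            rix = sorted(reserved_dmr)
            base[rix] = np.clip(base[rix], 0.15, 0.60)
            betas[rix, :] = base[rix][:, None]

    auto = np.flatnonzero(
        (np.array(chroms) != "chrX")
        & ~np.isin(np.arange(P), sorted(reserved_dmr))
    )
    special = rng_probe.permutation(auto)
    clock_ix = np.sort(special[:n_clock_probes])
    cellmix_ix = np.sort(special[n_clock_probes:n_clock_probes + n_cellmix_probes])
    sex_ix = np.flatnonzero(np.array(chroms) == "chrX")

    clock = None
    if n_clock_probes >= 2:
        clock_base = np.clip(base[clock_ix], 0.30, 0.70)
        clock, gamma, mean_score = make_toy_clock(
            [probe_ids[i] for i in clock_ix], clock_base, rng_clock
        )
        score = transform_age(ages, clock.adult_age)
        betas[clock_ix, :] = clock_base[:, None] + gamma[:, None] * (
            score[None, :] - mean_score
        )

    panel = None
    fractions = np.full((S, len(cell_types)), np.nan)
    if n_cellmix_probes >= len(cell_types) and len(cell_types) >= 2:
        K = len(cell_types)
        B = np.clip(
            rng_cell.choice([0.08, 0.5, 0.92], size=(n_cellmix_probes, K))
            + rng_cell.normal(0, 0.02, (n_cellmix_probes, K)),
            0.02,
            0.95,
        )
        fractions = rng_cell.dirichlet(np.full(K, 2.0), size=S)
        betas[cellmix_ix, :] = B @ fractions.T
        ref_t = 3000.0
        panel_probes = pd.Index([probe_ids[i] for i in cellmix_ix], name="probe_id")
        panel = ReferencePanel(
            mean_betas=pd.DataFrame(B, index=panel_probes, columns=list(cell_types)),
            m=pd.DataFrame(B * ref_t, index=panel_probes, columns=list(cell_types)),
            u=pd.DataFrame(
                np.maximum((1 - B) * ref_t - ALPHA, 0.0),
                index=panel_probes, columns=list(cell_types),
            ),
            design_type=pd.Series(design_type[cellmix_ix], index=panel_probes),
        )

    if len(sex_ix):
        male_level = np.clip(rng_probe.uniform(0.10, 0.25, len(sex_ix)), 0.03, 0.95)
        female_level = np.clip(male_level + 0.45, 0.03, 0.95)
        is_f = (sexes == "F")
        betas[np.ix_(sex_ix, np.arange(S))] = np.where(
            is_f[None, :], female_level[:, None], male_level[:, None]
        )

    if beta_noise_sd > 0:
        betas = betas + rng_noise.normal(0.0, beta_noise_sd, betas.shape)
    # cap below 1 - alpha/T_min so intensity emission stays exactly invertible
    betas = np.clip(betas, 0.0, 0.95)

    outlier_flags = np.zeros(S, dtype=bool)
    if n_outliers > 0:
        which = rng_out.choice(S, size=n_outliers, replace=False)
        outlier_flags[which] = True
        pooled_sd = max(float(betas.std()), 1e-6)
        n_shift = max(1, int(outlier_probe_frac * P))
        for j in which:
            rows = rng_out.choice(P, size=n_shift, replace=False)
            shift = outlier_shift_sd * pooled_sd * rng_out.choice([-1.0, 1.0])
            betas[rows, j] = np.clip(betas[rows, j] + shift, 0.0, 0.95)

    m, u, t = _emit_intensities(betas, design_type, rng_int, intensity_noise_sd)

    level = np.asarray(conversion_level, dtype=np.float64)
    if level.ndim == 0:
        level = np.full(S, float(level))
    ctrl_manifest, control = simulate_controls(
        S, level, conversion_noise_sd,
        seed=int(seeds[7].generate_state(1)[0] % (2**31)),
        sample_ids=sample_ids,
    )

    assay_manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "design_type": design_type,
            "channel": channel,
            "chromosome": chroms,
            "position": pos,
            "is_control": False,
            "control_category": "",
            "role": "",
        }
    )
    manifest = pd.concat([assay_manifest, ctrl_manifest], ignore_index=True)
    manifest["position"] = manifest["position"].astype(np.int64)

    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "reported_sex": sexes,
            "reported_age": ages,
            "batch": batch,
            "group": group,
        }
    )

    idx = pd.Index(probe_ids, name="probe_id")
    ds = SimulatedDataset(
        manifest=manifest,
        sample_sheet=sheet,
        betas=pd.DataFrame(betas, index=idx, columns=sample_ids),
        m=pd.DataFrame(m, index=idx, columns=sample_ids),
        u=pd.DataFrame(u, index=idx, columns=sample_ids),
        control=control,
        truth=SimTruth(
            seed=seed,
            ages=[float(x) for x in ages],
            sexes=[str(x) for x in sexes],
            cell_fractions=[[float(v) for v in row] for row in fractions],
            cell_types=list(cell_types),
            outlier_flags=[bool(x) for x in outlier_flags],
            conversion_levels=[float(x) for x in level],
            clock_probes=[probe_ids[i] for i in clock_ix],
            cellmix_probes=[probe_ids[i] for i in cellmix_ix],
            sex_probes=[probe_ids[i] for i in sex_ix],
        ),
        clock=clock,
        panel=panel,
        total=pd.DataFrame(t, index=idx, columns=sample_ids),
    )

    if dmr_regions:
        groups = sheet["group"].to_numpy()
        for rows, delta in dmr_regions:
            spike_bumps(ds, [[probe_ids[i] for i in rows]], delta, groups)
    return ds


def spike_bumps(
    dataset: SimulatedDataset,
    regions: list[list[str]],
    delta: float,
    group_assignment: np.ndarray,
) -> SimulatedDataset:
    """Add a group-specific beta shift on region probes (clipped to
    [0, 1]); intensities are re-emitted and the truth records the
    effective (post-clipping) shift."""
    grp = np.asarray(group_assignment).astype(bool)
    if grp.shape[0] != len(dataset.sample_ids):
        raise ValueError("group assignment length mismatch")
    for region in regions:
        if len(region) == 0:
            raise ValueError("region with zero probes")
        missing = [p for p in region if p not in dataset.betas.index]
        if missing:
            raise ValueError(f"region probe {missing[0]!r} not in dataset")
        rows = dataset.betas.index.get_indexer(region)
        before = dataset.betas.iloc[rows].to_numpy()
        shifted = before.copy()
        shifted[:, grp] = np.clip(before[:, grp] + delta, 0.0, 1.0)
        dataset.betas.iloc[rows] = shifted
        effective = float(
            (shifted[:, grp].mean() - before[:, grp].mean()) if grp.any() else 0.0
        )
        dataset.truth.dmrs.append(
            {
                "probe_ids": list(region),
                "delta": float(delta),
                "effective_delta": effective,
                "chromosome": str(
                    dataset.manifest.set_index("probe_id").loc[region[0], "chromosome"]
                ),
            }
        )
    # re-emit intensities from the updated betas using the stored totals
    t = dataset.total.to_numpy()
    b = dataset.betas.to_numpy()
    dataset.m.iloc[:, :] = b * t
    dataset.u.iloc[:, :] = np.maximum((1.0 - b) * t - ALPHA, 0.0)
    return dataset
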