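"""Sample-level QC: outlier detection, conversion controls, qual.

Plants one corrupted sample and one poorly bisulfite-converted sample
in a simulated cohort, then runs the full QC report and shows which
samples the default filters (outlyx consensus, bscon >= 85%,
qual RMSD <= 0.05) would remove.
"""

import tempfile
from pathlib import Path

import numpy as np

import methylstream as ms
from examples_util import store_from_dataset

levels = np.full(30, 0.98)
levels[7] = 0.70  # one failed conversion
ds = ms.simulate_dataset(
    P=2000, S=30, seed=9, n_outliers=1, conversion_level=levels,
)
tmp = Path(tempfile.mkdtemp())
store = store_from_dataset(tmp / "qc.h5", ds)

ms.quantile_normalize(store)  # needed for the qual metric
report = ms.run_qc(store, seed=1, norm_array="betas_norm")
f = report.frame

outlier_truth = ds.sample_ids[int(np.flatnonzero(ds.truth.outlier_flags)[0])]
print(f.loc[f["outlyx_flag"] | (f["bscon_pct"] < 85),
            ["sample_id", "outlyx_score", "outlyx_flag", "bscon_pct",
             "qual_rmsd"]].round(3).to_string(index=False))
print(f"\nplanted outlier: {outlier_truth}; planted low-conversion: "
      f"{ds.sample_ids[7]}")
print(f"samples failing default filters: {report.failed}")
print("outlyx_score near 1 marks a multivariate outlier in PC space;")
print("bscon below 85% indicates incomplete bisulfite conversion.")
store.close()
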