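"""Temporal filtering and nuisance removal for every session.

Re-runs the chain through the preprocessing stage: fourth-order zero-phase
Butterworth bandpass (0.008-0.10 Hz), 33 nuisance regressors per run
(15 tissue-PCA + 18 motion-derived), PCA reduction to 90% variance, OLS
removal.  Writes per-subject QC (mean framewise displacement, retained PC
count) and prints the summary; the emulated protocol reported 7.7 +/- 2.4
retained regressors per session.
"""

import pandas as pd

from netthin.pipeline import RunConfig, run_pipeline

CONFIG = RunConfig(outdir="results/pipeline", seed=7, log_level="WARNING",
                   stages=("simulate", "preproc"))

if __name__ == "__main__":
    run_pipeline(CONFIG)
    qc = pd.read_csv("results/pipeline/qc.csv")
    print(f"preprocessed {len(qc)} subjects (2 runs each)")
    print(f"mean framewise displacement {qc.mean_fd.mean():.3f} mm "
          f"(SD {qc.mean_fd.std():.3f})")
    print(f"retained nuisance PCs {qc.n_retained_pcs.mean():.1f} "
          f"+/- {qc.n_retained_pcs.std():.1f} of 33")
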