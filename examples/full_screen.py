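"""End-to-end synthetic screen: generate, analyze, compare to control.

Writes a 3-condition x 4-embryo screen (control; a hydrodynamic-length-
halved knockdown; a slowed-flow knockdown), runs every analysis stage,
and prints the per-condition report with significance flags.
"""

import tempfile
from pathlib import Path

import pandas as pd

from cortexflow import ScreenConfig, run_pipeline
from cortexflow.synthetic import synth_screen

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "screen"
    synth_screen(root, n_embryos=4, n_frames=60, seed=1)
    cfg = ScreenConfig(input_dir=root, output_dir=Path(tmp) / "out")
    report = run_pipeline(cfg)

    pd.set_option("display.width", 200)
    cols = ["vx_mean", "Tosc", "rho", "lambda", "lambda_se", "c",
            "sig_vx", "sig_tosc", "sig_lambda"]
    print(report.table[cols].round(3))
    print(
        "\nsig_* flags mark conditions whose statistic differs from the"
        " control (rank-sum at 99%/95%, or a normal z-test on the fitted"
        " material parameters). Only the lambda-halved condition should"
        " be flagged on lambda."
    )
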