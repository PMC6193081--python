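#!/usr/bin/env python
"""Calibrate on the treated arm, validate on the placebo arm.

Fits the induction triple plus the AP turnover rates to the treated-arm
cohort of stage 02, then predicts the placebo arm with the same parameters
and that arm's own (empty) protocol -- the transfer that justifies sharing
all surgery-driven rates across arms.  Reports fitted values against truth
and per-series weighted residuals; writes results/03_fit/.
"""

import json
from pathlib import Path

import numpy as np

from hiis.calibrate import cross_validate, fit
from hiis.dosing import appired_ii_protocol, placebo_protocol
from hiis.io import read_clinical_series
from hiis.model import ModelParameters

IN = Path(__file__).resolve().parent.parent / "results" / "02_cohort" / "clinical_series.csv"
OUT = Path(__file__).resolve().parent.parent / "results" / "03_fit"
SEED = 2018
FREE = ["r_induce_peak", "r_induce", "t_ap_delay", "k_ap_deg", "k_aps_deg"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = read_clinical_series(IN)
    by_branch = {b: [s for s in series if s.branch == b] for b in ("bIAP", "placebo")}
    truth = ModelParameters()

    result = fit(truth, by_branch["bIAP"], appired_ii_protocol(), free=FREE,
                 seed=SEED, max_evaluations=1500)
    print("calibration on the treated arm:")
    for name in FREE:
        t, e = truth.value(name), result.params.value(name)
        print(f"  {name:15s} truth={t:10.4g} fitted={e:10.4g} rel.err={(e - t) / t:+.1%}")
    print(f"  loss={result.total_loss:.4g} after {result.n_evaluations} evaluations")

    val = cross_validate(result, by_branch["placebo"], placebo_protocol())
    n_cal = sum(len(s.points) for s in by_branch["bIAP"])
    n_val = sum(v.size for v in val.values())
    cal_rms = (result.total_loss / n_cal) ** 0.5
    val_rms = (sum(float(np.sum(v**2)) for v in val.values()) / n_val) ** 0.5
    print(f"weighted RMS residual: calibration {cal_rms:.3f} vs validation {val_rms:.3f} "
          f"(per point; ~1 means within one MAE)")
    print("note: at cohort noise the induction *shape* (steepness/centre) is only weakly "
          "identified from 10 median points -- distant parameter combinations fit equally "
          "well; on noiseless data the triple is recovered exactly (see the test suite). "
          "The transfer to the placebo arm is what validates the shared-rate assumption.")

    result.params.to_yaml(OUT / "fitted_parameters.yaml")
    (OUT / "report.json").write_text(json.dumps({
        "free": FREE,
        "fitted": {n: result.params.value(n) for n in FREE},
        "truth": {n: truth.value(n) for n in FREE},
        "loss": result.total_loss,
        "calibration_rms": cal_rms,
        "validation_rms": val_rms,
        "validation_ssr_per_series": {k: float(np.sum(v**2)) for k, v in val.items()},
        "seed": SEED,
    }, indent=2))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
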