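"""Infer the fast-regime rates from the time-averaged efficiency
distribution.

At k = 100 1/s and 20 ms frames (k*tau = 2) idealization saturates, but the
shape of the per-frame efficiency distribution — point masses from
transitionless frames plus the Bessel-form continuous part — still encodes
both rates.  The global Bayesian model (shared emission means and noise,
per-dataset rates) is sampled with an affine-invariant ensemble; the summary
reports medians, 16-84% credible intervals and the MAP.

Run analysis/01_simulate_traces.py first.
"""

import json
from pathlib import Path

import pandas as pd

import smfretkit as sk
from smfretkit import io
from smfretkit.subres import infer_rates_global

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "traces"
TAU = 0.02


def main():
    traces = io.read_trace_set(SCRATCH / "fast" / "manifest.csv")
    pooled = sk.pooled_fret(traces)
    result = infer_rates_global([pooled], TAU, seed=1, max_burn=600)
    s = result.summary

    rows = []
    for i, name in enumerate(s.names):
        rows.append({"parameter": name, "median": s.median[i],
                     "ci16": s.ci16[i], "ci84": s.ci84[i],
                     "map": s.map_estimate[i]})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "subres_posterior.csv", index=False)
    (RESULTS / "subres_summary.json").write_text(json.dumps(
        {"burn_steps": int(s.burn_steps),
         "n_frames": int(pooled.size),
         "k1": s.interval("k1_0"), "k2": s.interval("k2_0")}, indent=1))

    lo1, m1, hi1 = s.interval("k1_0")
    lo2, m2, hi2 = s.interval("k2_0")
    print(f"{pooled.size} frames, burn-in {s.burn_steps} steps")
    print(f"k1 = {m1:.0f} [{lo1:.0f}, {hi1:.0f}] 1/s, "
          f"k2 = {m2:.0f} [{lo2:.0f}, {hi2:.0f}] 1/s "
          "(generating rates 100/100, invisible to 50 fps idealization)")


if __name__ == "__main__":
    main()
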