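"""Generate the synthetic smFRET trace sets used throughout the analysis.

Three regimes mirror the experimental sensors:
  * slow  — inter-subunit twisting-like kinetics (k_f = k_r = 1 1/s) sampled
            at 10 frames/s, where dwells are directly resolvable;
  * fast  — clamshell-like kinetics (k_f = k_r = 100 1/s) sampled at 50
            frames/s, far above the frame rate, where only the time-averaged
            efficiency distribution carries the rates;
  * bleach — slow kinetics with single-step photobleaching for the QC stage.

Writes summary tables to results/ and the bulky per-trace files to scratch/.
"""

import json
from pathlib import Path

import numpy as np

import smfretkit as sk
from smfretkit import io

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "traces"

REGIMES = {
    "slow": dict(k_f=1.0, k_r=1.0, eps=(0.38, 0.63), tau=0.1,
                 n_traces=100, n_frames=900, bleach_rate=None),
    "fast": dict(k_f=100.0, k_r=100.0, eps=(0.44, 0.66), tau=0.02,
                 n_traces=100, n_frames=900, bleach_rate=None),
    "bleach": dict(k_f=1.0, k_r=1.0, eps=(0.38, 0.63), tau=0.1,
                   n_traces=100, n_frames=900, bleach_rate=0.02),
}


def main():
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    for name, cfg in REGIMES.items():
        model = sk.KineticModel.two_state(cfg["k_f"], cfg["k_r"],
                                          *cfg["eps"], noise_sd=0.05)
        traces, truths = sk.simulate_trace_set(
            model, cfg["n_traces"], cfg["n_frames"], cfg["tau"],
            seed=SEED, bleach_rate=cfg["bleach_rate"], condition=name)
        outdir = SCRATCH / name
        io.write_trace_set(outdir, traces)
        io.write_truth(outdir / "truth.json", model, truths)
        pooled = sk.pooled_fret(traces)
        summary[name] = {
            "n_traces": cfg["n_traces"],
            "n_frames": cfg["n_frames"],
            "frame_period_s": cfg["tau"],
            "rates_per_s": [cfg["k_f"], cfg["k_r"]],
            "pooled_mean_E": float(pooled.mean()),
            "pooled_sd_E": float(pooled.std()),
            "stationary_high_occupancy": float(
                model.stationary_distribution()[1]),
            "n_bleached": int(sum(t.bleach_frame is not None for t in truths)),
        }
        print(f"{name:7s}: mean E {pooled.mean():.3f}, sd {pooled.std():.3f}, "
              f"{summary[name]['n_bleached']} bleached traces")
    (RESULTS / "trace_sets.json").write_text(json.dumps(summary, indent=1))
    print(f"trace sets under {SCRATCH}, summary in results/trace_sets.json")


if __name__ == "__main__":
    main()
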