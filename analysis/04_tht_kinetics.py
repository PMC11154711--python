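#!/usr/bin/env python
"""ThT aggregation kinetics: variant panel ordering and the seeding effect.

Fits four-parameter logistic growth curves to a synthetic kinetics panel
(fast aggregator, wild type, slow aggregator, non-aggregator), checks that
the fitted t50 ordering matches the generating ordering and that flat traces
are reported as "no detectable aggregation", then quantifies a seeded vs
unseeded pair generated with a 2-hour lag-time difference and a 1.3-fold
amplitude gain.

Writes results/tht_kinetics.tsv.
"""

import numpy as np

from foldscape.aggregation import fit_sigmoid, is_flat, seeding_effect
from foldscape.io import write_table
from foldscape.synthetic import NoiseSpec, ThTTruth, gen_tht_trace

GRID = np.linspace(0.0, 60.0, 121)

PANEL = {
    # name: (t50 h, k 1/h, amplitude); None = no aggregation
    "V173D": (6.0, 1.2, 1200.0),
    "wild_type": (14.0, 0.6, 1000.0),
    "F133A_slow": (30.0, 0.4, 700.0),
    "V173K_flat": None,
}


def main() -> None:
    rows = {"condition": [], "t50_h": [], "rate_k_per_h": [], "lag_h": [],
            "amplitude": []}
    for i, (name, truth) in enumerate(PANEL.items()):
        if truth is None:
            trace = gen_tht_trace(ThTTruth(100.0, 1.0, 20.0, 0.5), GRID,
                                  NoiseSpec(sigma=0.02, seed=300 + i))
            assert is_flat(trace)
            print(f"{name:>12}: no detectable aggregation "
                  "(amplitude below 5x baseline noise)")
            rows["condition"].append(name)
            for k in ("t50_h", "rate_k_per_h", "lag_h", "amplitude"):
                rows[k].append(np.nan)
            continue
        t50, k, amp = truth
        trace = gen_tht_trace(ThTTruth(100.0, amp, t50, k), GRID,
                              NoiseSpec(sigma=0.02, seed=300 + i))
        f = fit_sigmoid(trace)
        rows["condition"].append(name)
        rows["t50_h"].append(round(f.t50, 2))
        rows["rate_k_per_h"].append(round(f.rate_k, 3))
        rows["lag_h"].append(round(f.lag_time, 2))
        rows["amplitude"].append(round(f.amplitude, 1))
        print(f"{name:>12}: t50 = {f.t50:5.2f} h, k = {f.rate_k:.3f}/h, "
              f"lag = {f.lag_time:5.2f} h")

    fitted_t50 = [v for v in rows["t50_h"] if np.isfinite(v)]
    assert fitted_t50 == sorted(fitted_t50), "panel ordering not recovered"
    print("fitted t50 ordering matches the generating ordering")

    # seeding: 2-h lag reduction and 1.3x amplitude, as in cross-seeding runs
    unseeded = fit_sigmoid(gen_tht_trace(ThTTruth(100.0, 1000.0, 12.0, 1.0),
                                         GRID, NoiseSpec(sigma=0.02, seed=310)))
    seeded = fit_sigmoid(gen_tht_trace(ThTTruth(100.0, 1300.0, 10.0, 1.0),
                                       GRID, NoiseSpec(sigma=0.02, seed=311)))
    shift, ratio = seeding_effect(unseeded, seeded)
    print(f"seeding: lag reduced by {shift:.2f} h, amplitude x{ratio:.2f}")

    write_table(
        "results/tht_kinetics.tsv", rows,
        {"analysis": "ThT sigmoidal kinetics panel",
         "seeding_lag_shift_h": round(float(shift), 3),
         "seeding_amplitude_ratio": round(float(ratio), 3)},
    )


if __name__ == "__main__":
    main()
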