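"""Generate the two synthetic datasets used by the downstream analyses.

Writes one paired treadmill trial per protocol speed (force, IMU, marker
traces plus ground truth) and the default 96-runner outdoor cohort's
session table under results/simulated/.
"""

import json
from pathlib import Path

from runload.preprocess import write_trace
from runload.synthetic import (
    CohortParams,
    TreadmillParams,
    gen_outdoor_cohort,
    gen_treadmill_trial,
)
from runload.workflows import write_session_table

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for speed in (2.22, 3.33, 4.44):
        params = TreadmillParams(speed_mps=speed, n_steps=100, seed=SEED)
        force, imu, marker, truth = gen_treadmill_trial(params)
        trial_dir = OUT / f"treadmill_{speed:.2f}".replace(".", "_")
        trial_dir.mkdir(exist_ok=True)
        write_trace(force, trial_dir / "force.csv")
        write_trace(imu, trial_dir / "imu.csv")
        write_trace(marker, trial_dir / "marker.csv")
        (trial_dir / "truth.json").write_text(
            json.dumps(
                {
                    "speed_mps": truth.speed_mps,
                    "imu_lag_samples": truth.imu_lag_samples,
                    "n_steps": len(truth.stances),
                    "vgrf_peaks_bw": truth.vgrf_peaks_bw.tolist(),
                    "acc_v_peaks_g": truth.acc_v_peaks_g.tolist(),
                },
                indent=2,
            )
            + "\n"
        )
        print(f"treadmill trial at {speed:.2f} m/s: {len(truth.stances)} steps "
              f"-> {trial_dir}")

    records, truth = gen_outdoor_cohort(CohortParams(seed=SEED))
    write_session_table(records, OUT / "cohort_sessions.csv")
    (OUT / "cohort_truth.json").write_text(
        json.dumps(
            {
                "runner_mean_g": truth.runner_mean_g,
                "heavy_runners": list(truth.heavy_runners),
            },
            indent=2,
        )
        + "\n"
    )
    runners = len({r.runner_id for r in records})
    print(f"outdoor cohort: {len(records)} sessions of {runners} runners "
          f"({len(truth.heavy_runners)} heavy loading styles) -> {OUT}")


if __name__ == "__main__":
    main()
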