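"""Light-triggered drug release kinetics and photosensitizer photobleaching.

Simulates a subcutaneous injection of drug-loaded liposomes (lightly
scattering inclusion, reduced scattering 5 cm^-1 at 490 nm) imaged every
minute for 8 min while treatment light releases the drug along a
saturating time course.  The pipeline recovers optical properties once,
corrects each minute's fluorescence frame for attenuation, converts to
absolute concentration and detects the release plateau.  Photosensitizer
photobleaching across the treatment (1.57 -> 0.73 ug/mL ground truth) is
quantified as a percent change.

Writes results/release_kinetics.csv and results/release_summary.json.
"""

import json
from pathlib import Path

from sfdiq.experiments import release_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    res = release_experiment(seed=seed)
    series = res["series"]
    series.to_csv(OUT / "release_kinetics.csv")
    summary = {
        "start_ugml": round(float(series.mean_ugml[1]), 3),
        "end_ugml": round(float(series.mean_ugml[-1]), 3),
        "injected_ceiling_ugml": res["injected_ceiling_ugml"],
        "plateau_time_min": series.plateau_time_min,
        "pop_pre_ugml": round(res["pop_pre_ugml"], 3),
        "pop_post_ugml": round(res["pop_post_ugml"], 3),
        "photobleaching_pct": round(res["photobleaching_pct"], 2),
        "seed": seed,
    }
    (OUT / "release_summary.json").write_text(json.dumps(summary, indent=1))
    print("Drug release kinetics (ROI means, ug/mL):")
    for t, m, sd in zip(series.times_min, series.mean_ugml, series.sd):
        print(f"  t={t:4.0f} min  {m:6.2f} +/- {sd:.2f}")
    print(f"  plateau detected at t = {series.plateau_time_min} min")
    print(f"Photosensitizer photobleaching: {res['pop_pre_ugml']:.2f} -> "
          f"{res['pop_post_ugml']:.2f} ug/mL ({res['photobleaching_pct']:.1f}% decrease)")
    print(f"  tables -> {OUT / 'release_kinetics.csv'}")


if __name__ == "__main__":
    main()
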