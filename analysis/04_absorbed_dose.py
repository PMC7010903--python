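"""Assemble absorbed doses to the nucleus per added activity and scenario.

Uses the kinetics of a synthetic measurement realisation together with the
published per-day monolayer S values to compute the MIRD dose over the 4-h
uptake plus 6 follow-up days, for the internalized source in cytoplasm or
Golgi, and compares scenarios.  Writes results/absorbed_doses.csv.
"""
from pathlib import Path

import pandas as pd

from celldose import reference
from celldose.dosimetry import ColonyModel, colony_schedule, compute_absorbed_dose, monte_carlo_s_table
from celldose.kinetics import fit_uptake_curves, build_cumulated_table
from celldose.synthetic import SyntheticConfig, generate_uptake_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20250925


def main() -> None:
    cfg = SyntheticConfig()
    series, _, _ = generate_uptake_dataset(cfg, seed=SEED)
    s_table = reference.monolayer_s_per_day()
    print("colony sizes, days 1-6 (doubling time "
          f"{cfg.doubling_time_h} h): {colony_schedule(cfg.doubling_time_h)}")

    rows = []
    for a0, ser in series.items():
        model = fit_uptake_curves(ser, r2_flag_threshold=0.95)
        cum = build_cumulated_table(ser, model, a0_bq=a0 * 1e6)
        for scenario, where in (("pm_cy", "cytoplasm"), ("pm_g", "golgi")):
            res = compute_absorbed_dose(
                cum, s_table, scenario=scenario, internalized_in=where,
                added_activity_mbq_ml=a0,
            )
            rows.append(
                {
                    "activity_MBq_per_ml": a0,
                    "scenario": scenario,
                    "dose_Gy": res.total_dose_gy,
                    "dose_sd_Gy": res.total_sd_gy,
                    "uptake_medium_share": res.table.loc["uptake", "medium"]
                    / res.total_dose_gy,
                }
            )
    # truncated-cone scenario with engine-computed per-day S values
    from celldose.geometry import TruncatedConeCell, build_well
    from celldose.transport import TransportEngine

    engine = TransportEngine()
    tc_table = monte_carlo_s_table(
        engine,
        TruncatedConeCell.reference(),
        ColonyModel(cfg.doubling_time_h),
        well=build_well(cfg.medium_volume_ml),
        n_histories=20_000,
        seed=SEED % 2**31,
    )
    for a0, ser in series.items():
        model = fit_uptake_curves(ser, r2_flag_threshold=0.95)
        cum = build_cumulated_table(ser, model, a0_bq=a0 * 1e6)
        res = compute_absorbed_dose(
            cum, tc_table, scenario="tc_cy", internalized_in="cytoplasm",
            added_activity_mbq_ml=a0,
        )
        rows.append(
            {
                "activity_MBq_per_ml": a0,
                "scenario": "tc_cy",
                "dose_Gy": res.total_dose_gy,
                "dose_sd_Gy": res.total_sd_gy,
                "uptake_medium_share": res.table.loc["uptake", "medium"]
                / res.total_dose_gy,
            }
        )

    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "absorbed_doses.csv", index=False)
    print(table.to_string(index=False))
    wide = table.pivot(index="activity_MBq_per_ml", columns="scenario", values="dose_Gy")
    print("\nGolgi vs cytoplasm localisation raises the total dose by "
          f"{100 * (wide['pm_g'] / wide['pm_cy'] - 1).mean():.0f}% on average;")
    print("the unbound medium contributes ~"
          f"{100 * table['uptake_medium_share'].mean():.0f}% of the total, all "
          "during the 4-h incubation.")


if __name__ == "__main__":
    main()
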