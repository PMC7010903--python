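"""Consistency arithmetic on the published S-value and dose tables.

Recomputes the headline numbers that follow from the printed tables alone:
mean mesh-cell S values, the Golgi-vs-cytoplasm enhancement, the CSG Golgi
comparison, day-1 monolayer consistency, and the sphere-to-mesh cumulative
dose ratios.  Writes results/published_table_checks.csv.
"""
from pathlib import Path

import pandas as pd

from celldose import reference

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    mesh = reference.mesh_cell_self_s()
    pct = reference.golgi_vs_cytoplasm_percent()
    csg = reference.golgi_s_comparison()
    doses = reference.cumulative_dose_per_activity()
    day = reference.monolayer_s_per_day()

    rows = [
        ("mean mesh S(N<-Cy) [Gy/Bq s]", mesh["s_cy"].mean()),
        ("mean mesh S(N<-G)  [Gy/Bq s]", mesh["s_g"].mean()),
        ("mean mesh S(N<-CS) [Gy/Bq s]", mesh["s_cs"].mean()),
        ("Golgi vs cytoplasm, mean increase [%]", pct.mean()),
        ("Golgi vs cytoplasm, max increase [%]", pct.max()),
        ("cell with max Golgi increase", float(pct.idxmax())),
        ("mean CSG half-torus S(N<-G) [Gy/Bq s]", csg["s_g_csg"].mean()),
        ("mean mesh-Golgi S(N<-G) [Gy/Bq s]", csg["s_g_pm"].mean()),
        ("day-1 monolayer S(N<-CS) [Gy/Bq s]", day.loc["day1", "s_cs"]),
        ("sphere/mesh dose ratio @0.1 MBq/ml", doses.loc[0.1, "sphere"] / doses.loc[0.1, "pm_cy"]),
        ("sphere/mesh dose ratio @2.5 MBq/ml", doses.loc[2.5, "sphere"] / doses.loc[2.5, "pm_cy"]),
        ("Golgi/cytoplasm dose ratio @0.5 MBq/ml", doses.loc[0.5, "pm_g"] / doses.loc[0.5, "pm_cy"]),
    ]
    table = pd.DataFrame(rows, columns=["quantity", "value"])
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "published_table_checks.csv", index=False)
    print(table.to_string(index=False))
    print("\nKey findings: relocating the internalized source from cytoplasm to")
    print("Golgi raises the nuclear self-dose by ~64% on average (up to +149%);")
    print("spherical cell models predict ~3x the mesh-model absorbed dose.")


if __name__ == "__main__":
    main()
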