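"""Selectivity index over time, per mouse and averaged by sex.

Computes the cumulative-window SI on the 10-minute grid for every focal
mouse from the reconstructed occupancy, then the pointwise group mean
with a t-based 95% confidence band, separately for females and males.
Writes the per-mouse series and the group summaries; prints the early
dynamics (the high 10-minute value that reflects lack of exploration
rather than choice, and the ~90-minute minimum) and the overall SI.

Requires 02_reconstruct_occupancy.py to have run.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from prefwatch import gendist, rfid, selectivity

EXP = Path(__file__).resolve().parent.parent / "results" / "experiment"


def load_occupancy(fid: str) -> rfid.Occupancy:
    layout = rfid.AntennaLayout(focal_id=fid)
    df = pd.read_csv(EXP / "occupancy" / f"{fid}.csv")
    codes = {name: i for i, name in enumerate(rfid.CAGE_NAMES)}
    occ = rfid.Occupancy(
        cages=df["cage"].map(codes).to_numpy(),
        start_h=df["start_h"].to_numpy(),
        end_h=df["end_h"].to_numpy(),
        layout=layout,
    )
    occ.validate()
    return occ


def main() -> None:
    design = json.loads((EXP / "design.json").read_text())
    cohort = gendist.parse_genotype_table(EXP / "genotypes.csv")

    series = {}
    overall = []
    for fid in design["focals"]:
        occ = load_occupancy(fid)
        series[fid] = selectivity.si_series(occ, mouse_id=fid)
        overall.append(
            {"focal_id": fid, "sex": cohort[fid].sex, "overall_si": selectivity.overall_si(occ)}
        )
    pd.concat([s.to_frame() for s in series.values()]).to_csv(
        EXP / "si_series.csv", index=False
    )
    overall_df = pd.DataFrame(overall)
    overall_df.to_csv(EXP / "si_overall.csv", index=False)

    summaries = []
    for sex in ("F", "M"):
        group = [series[fid] for fid in design["focals"] if cohort[fid].sex == sex]
        mean = selectivity.group_mean_si(group)
        mean.insert(0, "sex", sex)
        summaries.append(mean)
    pd.concat(summaries).to_csv(EXP / "si_group_means.csv", index=False)

    allmean = selectivity.group_mean_si(list(series.values()))
    at = lambda t: allmean.loc[np.argmin(np.abs(allmean["t_h"] - t)), "mean_si"]
    print(f"mean SI after 10 min: {at(1 / 6):.2f} (exploration artefact, not choice)")
    print(f"mean SI after 90 min: {at(1.5):.2f}")
    print(f"mean SI at run end:   {at(136.0):.2f}")
    for sex, label in (("F", "females"), ("M", "males")):
        m = overall_df.loc[overall_df["sex"] == sex, "overall_si"].mean()
        print(f"mean overall SI, {label}: {m:.2f}")


if __name__ == "__main__":
    main()
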