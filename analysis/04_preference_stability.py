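"""Preference blocks, stability summaries, and chance-match tests.

For every focal mouse: the preferred-cage series on the 10-minute grid,
its segmentation into preference blocks, the final preference and the
share of social time spent with it, and whether the early preference
(10 min, 90 min, 24 h) already matched the final choice. The cohort
match counts are tested against the 1-in-4 chance expectation with the
chi-square goodness-of-fit test (Yates-corrected and uncorrected).

Requires 02_reconstruct_occupancy.py to have run.
"""

import importlib
import json
from pathlib import Path

import pandas as pd

from prefwatch import gendist, preference, rfid

EXP = Path(__file__).resolve().parent.parent / "results" / "experiment"
load_occupancy = importlib.import_module("03_selectivity_dynamics").load_occupancy


def main() -> None:
    design = json.loads((EXP / "design.json").read_text())
    cohort = gendist.parse_genotype_table(EXP / "genotypes.csv")

    rows = []
    for fid in design["focals"]:
        occ = load_occupancy(fid)
        series = preference.preferred_cage_series(occ)
        blocks = preference.segment_blocks(series)
        final = preference.final_preference(occ)
        summ = rfid.compute_durations(occ)
        sat = summ.satellite_totals_h
        matches = preference.match_at(series, occ)
        rows.append(
            {
                "focal_id": fid,
                "sex": cohort[fid].sex,
                "final_cage": final.cage if final else None,
                "preferred_share_of_social": sat.max() / sat.sum() if sat.sum() else None,
                "n_blocks": blocks.n_blocks if blocks else None,
                "last_block_fraction": blocks.last_block_fraction if blocks else None,
                "stabilization_h": blocks.stabilization_time_h if blocks else None,
                **{
                    f"match_{int(round(m.checkpoint_h * 60))}min": m.matched for m in matches
                },
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(EXP / "blocks.csv", index=False)

    print(f"mean preferred-cage share of social time: "
          f"{100 * df['preferred_share_of_social'].mean():.1f}%")
    print(f"mean number of preference blocks: {df['n_blocks'].mean():.1f} "
          f"(females {df[df.sex == 'F']['n_blocks'].mean():.1f}, "
          f"males {df[df.sex == 'M']['n_blocks'].mean():.1f})")
    print(f"mean last-block share of defined grid points: "
          f"{df['last_block_fraction'].mean():.1f}%")

    tests = []
    n = len(df)
    for col, label in (
        ("match_10min", "10 min"),
        ("match_90min", "90 min"),
        ("match_1440min", "24 h"),
    ):
        matched = int(df[col].sum())
        for yates in (True, False):
            t = preference.chance_match_test(matched, n, yates=yates)
            tests.append(
                {
                    "checkpoint": label,
                    "n_matched": matched,
                    "n_total": n,
                    "expected": t.expected,
                    "yates": yates,
                    "chi2": t.statistic,
                    "p": t.p,
                }
            )
        print(f"matches at {label}: {matched}/{n} (chance expectation {n / 4:.2f})")
    pd.DataFrame(tests).to_csv(EXP / "match_tests.csv", index=False)


if __name__ == "__main__":
    main()
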