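#!/usr/bin/env python
"""Response-surface ANOVA, cube plots and the media-behaviour comparison.

Consumes the run table produced by 04_campaign.py, fits full and reduced
quadratic response surfaces per response and media block, prints the
significance screening, writes corner ("cube-plot") prediction tables
panelled by fibrous-tissue stiffness, and evaluates the paired isotropic vs
anisotropic media comparison.

Outputs under results/anova/:
  anova_{PPS,PCS}_{media}.csv       full-model term tables
  reduced_{PPS,PCS}_{media}.csv     backward-eliminated models
  cubes_{PPS,PCS}_{media}.csv       16-corner predicted responses
  media_ttest.csv                   paired t-test per response
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from plaquestress import doe_engine as de

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = RESULTS / "anova"


def main():
    runs_path = RESULTS / "campaign" / "runs.csv"
    if not runs_path.exists():
        sys.exit("run analysis/04_campaign.py first (results/campaign/runs.csv missing)")
    runs = pd.read_csv(runs_path)
    OUT.mkdir(parents=True, exist_ok=True)

    ttest_rows = []
    for resp in ("PPS", "PCS"):
        for mb in runs.media_behaviour.unique():
            sub = runs[runs.media_behaviour == mb].dropna(subset=[resp])
            full = de.fit_response_surface(sub, resp)
            red = de.fit_response_surface(sub, resp, reduce=True)
            full.anova.to_csv(OUT / f"anova_{resp}_{mb}.csv", index=False)
            red.anova.to_csv(OUT / f"reduced_{resp}_{mb}.csv", index=False)
            de.cube_summary(full).to_csv(OUT / f"cubes_{resp}_{mb}.csv", index=False)
            sig = full.anova[full.anova.near_significant]
            print(f"\n{resp}, {mb} media: R^2 = {full.r_squared:.3f}, "
                  f"residual normality p = {full.normality_p:.3f}")
            for row in sig.itertuples():
                print(f"   {row.term:8s} p = {row.p_value:.4f} ({row.kind})")
        mbs = list(runs.media_behaviour.unique())
        if len(mbs) == 2:
            a = runs[runs.media_behaviour == mbs[0]].sort_values("block_run")
            b = runs[runs.media_behaviour == mbs[1]].sort_values("block_run")
            merged = a.merge(b, on="block_run", suffixes=("_a", "_b")).dropna(
                subset=[f"{resp}_a", f"{resp}_b"])
            tt = de.paired_t_test(merged[f"{resp}_a"], merged[f"{resp}_b"])
            ttest_rows.append({"response": resp, "mean_difference_kpa": tt.mean_difference,
                               "p_value": tt.p_value, "n_pairs": tt.n})
            print(f"   {mbs[0]} vs {mbs[1]} media: mean {resp} difference "
                  f"{tt.mean_difference:+.2f} kPa, p = {tt.p_value}")
    pd.DataFrame(ttest_rows).to_csv(OUT / "media_ttest.csv", index=False)
    print(f"\n-> {OUT}")


if __name__ == "__main__":
    main()
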