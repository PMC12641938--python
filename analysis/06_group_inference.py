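#!/usr/bin/env python
"""Group-level inference: ANOVA + Tukey HSD on published and synthetic data.

Part A reproduces the inference that is fully recomputable from print: the
five-group tear-angle Tukey HSD from the published summaries (n = 5 per
group). Part B runs the same machinery on the synthetic cohort tables
written by scripts 02-05, and correlates competency with experience.
"""

import pandas as pd

import surgaze as sg
from common import RESULTS
from surgaze import stats as st

METRIC_FILES = {
    "mean_fixation_duration": ("session_gaze_metrics.csv", "mean_fixation_duration"),
    "mean_saccade_amplitude": ("session_gaze_metrics.csv", "mean_saccade_amplitude"),
    "hud_share": ("gaze_distribution.csv", "hud"),
    "coverage_fraction": ("coverage.csv", "covered_fraction_frame"),
    "tear_angle": ("tear_metrics.csv", "tear_angle"),
    "diameter_fraction": ("tear_metrics.csv", "diameter_fraction"),
}


def printed_table_inference() -> pd.DataFrame:
    res = st.anova_oneway_from_summary(sg.TEAR_ANGLE_SUMMARIES)
    print("published tear-angle table: "
          f"F({res.df_between}, {res.df_within}) = {res.F:.1f}, p = {res.p:.3g}")
    tk = st.tukey_hsd_from_summary(sg.TEAR_ANGLE_SUMMARIES)
    rows = [
        {"group_i": p.label_i, "group_j": p.label_j, "mean_diff": p.mean_diff,
         "q": p.q, "p": p.p, "significant": p.significant}
        for p in tk.pairs
    ]
    df = pd.DataFrame(rows)
    for p in tk.pairs:
        if p.significant:
            print(f"  {p.label_i} vs {p.label_j}: q = {p.q:.2f}, p = {p.p:.2g}")
    return df


def synthetic_cohort_inference() -> pd.DataFrame:
    rows = []
    for metric, (fname, col) in METRIC_FILES.items():
        path = RESULTS / fname
        if not path.exists():
            raise SystemExit(
                f"missing {path}; run the earlier numbered scripts first"
            )
        df = pd.read_csv(path)
        groups = [
            st.GroupSummary(lab, int(sub[col].notna().sum()),
                            float(sub[col].mean()), float(sub[col].std(ddof=1)))
            for lab, sub in df.groupby("label", sort=False)
        ]
        res = st.anova_oneway_from_summary(groups)
        rows.append({"metric": metric, "F": res.F, "df_between": res.df_between,
                     "df_within": res.df_within, "p": res.p})
    return pd.DataFrame(rows)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    printed = printed_table_inference()
    printed.to_csv(RESULTS / "inference_tear_angle_printed.csv", index=False)

    anova = synthetic_cohort_inference()
    anova.to_csv(RESULTS / "inference_synthetic_anova.csv", index=False)
    print("\nsynthetic-cohort one-way ANOVA per metric:")
    print(anova.round(4).to_string(index=False))

    x = [sg.EXPERIENCE_ORDINALS[g.label] for g in sg.ICO_OSCAR_SUMMARIES]
    y = [g.mean for g in sg.ICO_OSCAR_SUMMARIES]
    corr = st.pearson_correlation(x, y)
    print(f"\ncompetency-score group means vs experience ordinal: "
          f"r = {corr.r:.3f} (r^2 = {corr.r_squared:.3f}, n = {corr.n} groups)")


if __name__ == "__main__":
    main()
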