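"""Run the statistical battery on the atypicality table.

Per family (Holm-corrected separately): the four preterm-vs-term group
comparisons (Mann–Whitney U with Vargha–Delaney A), the four GA
correlations per group, and the index × outcome Spearman grid per group.
Indices whose outcome correlation survives in the preterm group are
followed up with the adjusted multiple regression (index + GA + sex +
motion + IMD), bootstrap 95% CIs for the adjusted R² (1000 replications),
out-of-bag bootstrap prediction R² (100 resamples), and the
influential-observation sensitivity rerun.
"""

import argparse

from neonorm.atypicality import read_atypicality_tsv
from neonorm.stats import BatteryConfig, run_full_battery

from common import DEFAULT_SEED, RESULTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    table = read_atypicality_tsv(RESULTS / "atypicality.tsv")
    report = run_full_battery(
        table, BatteryConfig(alpha=args.alpha, seed=args.seed)
    )
    report.to_tsv(RESULTS / "stats_report.tsv")

    t = report.tests
    sig = t[t["reject"]]
    print(f"{len(t)} tests, {len(sig)} Holm-significant at α={args.alpha}:")
    for _, row in sig.iterrows():
        print(f"  [{row['family']}/{row['group']}] {row['test']}: "
              f"{row['effect_name']}={row['effect']:.3f}, "
              f"p_holm={row['p_holm']:.4g}")
    for label, model in report.models.items():
        lo, hi = model.adj_r2_ci
        print(f"model {label}: adj R²={model.adj_r2:.3f} "
              f"[{lo:.3f}, {hi:.3f}], F({model.f_dof[0]},{model.f_dof[1]})="
              f"{model.f_statistic:.2f}, p={model.f_p_value:.4g}, "
              f"prediction R²={model.prediction_adj_r2:.3f}")
    for test, (full, trimmed, dropped) in report.sensitivity.items():
        print(f"sensitivity {test}: rho {full.effect:.3f} -> "
              f"{trimmed.effect:.3f} after dropping {len(dropped)} "
              f"influential observation(s)")
    print(f"report written to {RESULTS / 'stats_report.tsv'}")


if __name__ == "__main__":
    main()
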