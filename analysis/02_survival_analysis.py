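"""Kaplan-Meier summaries, Gompertz fits, and the four survival tests.

Reads results/lifespan.csv (from 01_simulate_lifespan.py), merges the two
control groups per sex, and produces the summary table (median and
90%-mortality ages, MRDT, alpha, R0, R^2, N, percent deltas versus control)
plus per-comparison results of the modified KS, log-rank,
Gehan-Breslow-Wilcoxon, and Wang-Allison tests.

Writes results/lifespan_summary.tsv, results/lifespan_tests.tsv, and
results/lifespan_report.json.
"""

from radspan.pipeline import RunConfig, run_lifespan_pipeline

CONTROL_MAP = {
    f"{sex}_{dose}cGy": f"{sex}_ctrl_low" if dose <= 10 else f"{sex}_ctrl_high"
    for sex in ("m", "f") for dose in (5, 10, 20, 40)
}


def main() -> None:
    cfg = RunConfig(lifespan_csv="results/lifespan.csv", out_dir="results",
                    control_map=CONTROL_MAP, merge_controls=True)
    report = run_lifespan_pipeline(cfg)
    print(f"{len(report.outputs['summaries'])} group summaries, "
          f"{len(report.outputs['tests'])} test results -> results/")
    for s in sorted(report.outputs["summaries"], key=lambda s: (s.sex, s.dose_cgy)):
        dm = "-" if s.delta_median_pct is None else f"{s.delta_median_pct:+.1f}%"
        print(f"  {s.group:<16} M={s.median:.0f} d ({dm})  90%={s.age90:.0f} d  "
              f"MRDT={s.mrdt_days:.2f} d  alpha={s.alpha:.3f}  n={s.n}")
    sig = [t for t in report.outputs["tests"] if t.p_value < 0.05]
    print(f"{len(sig)} of {len(report.outputs['tests'])} tests significant at 0.05")


if __name__ == "__main__":
    main()
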