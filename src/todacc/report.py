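"""Human-readable rendering and CSV export of a cohort comparison.

Display rounding follows reporting convention — minutes to integers,
contrast estimates to one decimal — while every CSV export keeps full
precision.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import CohortReport

__all__ = ["render_markdown", "write_outputs"]


def render_markdown(report: CohortReport) -> str:
    lines: list[str] = []
    lines.append("# Cut-point method comparison")
    lines.append("")
    lines.append(
        f"Files read: {report.n_files}; parseable: {report.n_parsed}; "
        f"meeting wear-time criteria under all methods: {report.n_included}"
    )
    if report.n_included == 0:
        lines.append("")
        lines.append("0 included subjects — no comparison possible.")
        return "\n".join(lines) + "\n"
    wear = ", ".join(
        f"{m}: {report.cohort_mean_weartime_min[m] / 60:.1f} h" for m in report.methods
    )
    lines.append(f"Mean valid days: {report.mean_valid_days:.1f}; cohort mean wear time: {wear}")
    lines.append("")

    lines.append("## Adjusted daily minutes, mean (SD), per cut-point method")
    lines.append("")
    header = "| PA level | " + " | ".join(report.methods) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(report.methods) + 1))
    for outcome in ["MVPA", "LPA", "TPA", "SB"]:
        cells = []
        for m in report.methods:
            row = report.table3[
                (report.table3["outcome"] == outcome) & (report.table3["method"] == m)
            ].iloc[0]
            cells.append(f"{row['mean_min']:.0f} ({row['sd_min']:.0f})")
        lines.append(f"| {outcome} | " + " | ".join(cells) + " |")
    lines.append("")

    lines.append("## Pairwise contrasts (Bonferroni-corrected)")
    lines.append("")
    lines.append("| PA level | Comparison | Estimate | SE | t | p | 95% CI |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in report.contrasts.iterrows():
        p = "< 0.0001" if r["p_bonf"] < 1e-4 else f"{r['p_bonf']:.4g}"
        lines.append(
            f"| {r['outcome']} | {r['pair']} | {r['estimate']:.1f} | {r['se']:.1f} "
            f"| {r['t']:.1f} | {p} | [{r['ci_low']:.2f}, {r['ci_high']:.2f}] |"
        )
    lines.append("")

    lines.append("## Repeated-measures ANOVA")
    lines.append("")
    for outcome, res in report.anova.items():
        p = "< 0.0001" if res.p_value < 1e-4 else f"{res.p_value:.4g}"
        lines.append(
            f"- {outcome}: F({res.df_method}, {res.df_error}) = {res.f_stat:.1f}, "
            f"p {p} (GG epsilon {res.gg_epsilon:.2f})"
        )
    lines.append("")

    lines.append("## WHO-guideline adherence")
    lines.append("")
    lines.append("| Method | ≥180 min TPA (%) | SB bouts < 1 h (%) | n |")
    lines.append("|---|---|---|---|")
    for _, r in report.adherence.iterrows():
        lines.append(
            f"| {r['method']} | {r['pct_meets_tpa']:.0f} | "
            f"{r['pct_meets_sb_bout_rule']:.0f} | {int(r['n'])} |"
        )
    if len(report.adherence_tests):
        lines.append("")
        lines.append("McNemar tests on TPA adherence:")
        for _, r in report.adherence_tests.iterrows():
            p = "< 0.001" if r["p_value"] < 1e-3 else f"{r['p_value']:.3g}"
            lines.append(
                f"- {r['pair']}: discordant {int(r['n_a_only'])}/{int(r['n_b_only'])}, p {p}"
            )
    return "\n".join(lines) + "\n"


def write_outputs(report: CohortReport, out_dir) -> None:
    """Write full-precision CSVs and the Markdown report into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table3.to_csv(out / "adjusted_minutes_by_method.csv", index=False)
    report.contrasts.to_csv(out / "pairwise_contrasts.csv", index=False)
    report.adherence.to_csv(out / "adherence.csv", index=False)
    report.adherence_tests.to_csv(out / "adherence_tests.csv", index=False)
    for method, df in report.subject_summaries.items():
        df.to_csv(out / f"subject_summaries_{method}.csv", index=False)
    (out / "report.md").write_text(render_markdown(report))
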