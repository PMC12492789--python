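"""End-to-end orchestration: counts → daily minutes → cohort comparison.

For each subject and each cut-point set the chain is

1. truncate the 1-s stream to the wear protocol ± margin,
2. reintegrate to 60 s and detect non-wear on the minute-level vector
   magnitude (Choi rule),
3. reintegrate the same truncated stream to the set's calibration epoch
   (recomputed from the 1-s stream per method, never resampled from another
   epoch length), project the non-wear mask and classify,
4. accumulate per-day wear and intensity minutes.

Cohort-level steps (per cut-point set): the 4-day/6-h validity filter,
subject means over valid days, wear-time standardization, and guideline
adherence.  Methods are then compared on the subjects valid under *every*
set (complete cases): repeated-measures ANOVA and Bonferroni pairwise
contrasts per outcome, and exact McNemar tests on the TPA-adherence flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as cls
from . import ingest, nonwear, standardize, stats
from .classification import CutPointSet
from .config import PipelineConfig
from .ingest import CountsTimeSeries, ProtocolWindow

__all__ = ["process_recording", "run_pipeline", "CohortReport", "read_protocol_csv"]

logger = logging.getLogger("todacc")

OUTCOMES = ["sb", "lpa", "mvpa", "tpa"]


@dataclass
class CohortReport:
    """Everything the cohort comparison produces, full precision."""

    methods: list
    n_files: int
    n_parsed: int
    n_included: int  # subjects valid under every cut-point set
    cohort_mean_weartime_min: dict  # method -> minutes
    mean_valid_days: float
    table3: pd.DataFrame  # outcome x method mean/sd of adjusted minutes
    contrasts: pd.DataFrame  # outcome, pair, estimate, se, t, p_bonf, ci
    anova: dict  # outcome -> RmAnovaResult
    adherence: pd.DataFrame  # method, pct_tpa, pct_sb_bout, n
    adherence_tests: pd.DataFrame  # pair, p_value, discordant counts
    subject_summaries: dict = field(default_factory=dict)  # method -> DataFrame


def read_protocol_csv(path) -> dict[str, ProtocolWindow]:
    """Read the wear-protocol log (``subject_id,start,end``)."""
    df = pd.read_csv(path)
    expected = ["subject_id", "start", "end"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    out: dict[str, ProtocolWindow] = {}
    for _, row in df.iterrows():
        out[str(row["subject_id"])] = ProtocolWindow(
            np.datetime64(pd.Timestamp(row["start"]), "s"),
            np.datetime64(pd.Timestamp(row["end"]), "s"),
        )
    return out


def process_recording(
    ts: CountsTimeSeries,
    protocol: ProtocolWindow,
    cps: CutPointSet,
    nonwear_params: nonwear.NonwearParams = nonwear.NonwearParams(),
    margin_min: float = 60.0,
) -> pd.DataFrame:
    """Daily summaries for one subject under one cut-point set."""
    trunc = ingest.truncate_to_protocol(ts, protocol, margin_min)
    if len(trunc) == 0:
        return cls.daily_summaries(pd.DataFrame(), ts.subject_id, cps.epoch_len_s)
    minutes = ingest.reintegrate(trunc, 60)
    intervals = nonwear.detect_nonwear_choi(minutes, nonwear_params)
    epochs = ingest.reintegrate(trunc, cps.epoch_len_s)
    epochs = nonwear.apply_nonwear_mask(epochs, intervals)
    labeled = cls.classify_series(epochs, cps)
    return cls.daily_summaries(labeled, ts.subject_id, cps.epoch_len_s)


def _iter_cohort_files(config: PipelineConfig):
    counts_dir = Path(config.counts_dir)
    files = sorted(counts_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no counts CSV files found in {counts_dir}")
    protocols = read_protocol_csv(config.protocol_csv)
    for f in files:
        subject_id = f.stem
        if subject_id not in protocols:
            logger.warning("%s: no protocol row; skipped", subject_id)
            continue
        yield subject_id, f, protocols[subject_id]


def run_pipeline(config: PipelineConfig, recordings=None) -> CohortReport:
    """Run the full comparison.

    ``recordings`` may be an iterable of ``(CountsTimeSeries,
    ProtocolWindow)`` pairs (e.g. straight from the simulator, avoiding
    file I/O); otherwise counts CSVs are read from ``config.counts_dir``.
    """
    sets = config.cutpoint_sets()
    dailies: dict[str, list[pd.DataFrame]] = {c.name: [] for c in sets}
    n_files = n_parsed = 0

    if recordings is None:
        source = _iter_cohort_files(config)

        def load():
            nonlocal n_files
            for subject_id, f, window in source:
                n_files += 1
                try:
                    yield ingest.read_counts_csv(f, subject_id), window
                except ingest.CountsValidationError as exc:
                    logger.warning("dropping %s: %s", subject_id, exc)

        pairs = load()
    else:
        def count_files(rs):
            nonlocal n_files
            for r in rs:
                n_files += 1
                yield r

        pairs = count_files(recordings)

    for ts, window in pairs:
        n_parsed += 1
        for cps in sets:
            dailies[cps.name].append(
                process_recording(ts, window, cps, config.nonwear, config.margin_min)
            )

    method_names = [c.name for c in sets]
    per_method: dict[str, pd.DataFrame] = {}
    included_sets = []
    for name in method_names:
        all_days = (
            pd.concat(dailies[name], ignore_index=True)
            if dailies[name]
            else cls.daily_summaries(pd.DataFrame(), "", 60)
        )
        flagged, included = standardize.filter_valid(all_days, config.validity)
        per_method[name] = flagged
        included_sets.append(set(included))

    common = sorted(set.intersection(*included_sets)) if included_sets else []
    logger.info(
        "attrition: %d files, %d parsed, %d meeting wear-time criteria under all methods",
        n_files,
        n_parsed,
        len(common),
    )

    summaries: dict[str, pd.DataFrame] = {}
    cohort_wear: dict[str, float] = {}
    adherence: dict[str, pd.DataFrame] = {}
    for name in method_names:
        means = standardize.subject_means(per_method[name], common)
        adj, cohort_mean = standardize.adjust_weartime(means)
        summaries[name] = adj
        cohort_wear[name] = cohort_mean
        adherence[name] = standardize.assess_adherence(
            adj,
            config.tpa_threshold_min,
            config.sb_bout_limit_min,
            config.use_adjusted_adherence,
        )

    n = len(common)
    table3_rows = []
    for outcome in OUTCOMES:
        col = f"{outcome}_adj_min"
        for name in method_names:
            vals = summaries[name][col] if n else pd.Series(dtype=float)
            table3_rows.append(
                {
                    "outcome": outcome.upper(),
                    "method": name,
                    "mean_min": float(vals.mean()) if n else float("nan"),
                    "sd_min": float(vals.std(ddof=1)) if n > 1 else float("nan"),
                }
            )
    table3 = pd.DataFrame(table3_rows)

    contrast_rows = []
    anova: dict[str, stats.RmAnovaResult] = {}
    adherence_rows = []
    adh_test_rows = []
    if n >= 2 and len(method_names) >= 2:
        for outcome in OUTCOMES:
            col = f"{outcome}_adj_min"
            matrix = np.column_stack(
                [summaries[name].set_index("subject_id").loc[common, col] for name in method_names]
            )
            try:
                anova[outcome.upper()] = stats.rm_anova(matrix)
            except stats.DegenerateDataError as exc:
                logger.warning("RM-ANOVA degenerate for %s: %s", outcome, exc)
            for c in stats.emm_pairwise(matrix, method_names):
                contrast_rows.append(
                    {
                        "outcome": outcome.upper(),
                        "pair": f"{c.pair[0]} - {c.pair[1]}",
                        "estimate": c.estimate,
                        "se": c.se,
                        "t": c.t_value,
                        "p_bonf": c.p_bonf,
                        "ci_low": c.ci_low,
                        "ci_high": c.ci_high,
                    }
                )
        flags = {
            name: adherence[name].set_index("subject_id").loc[common] for name in method_names
        }
        for name in method_names:
            adherence_rows.append(
                {
                    "method": name,
                    "pct_meets_tpa": 100.0 * float(flags[name]["meets_tpa_180"].mean()),
                    "pct_meets_sb_bout_rule": 100.0
                    * float(flags[name]["meets_sb_bout_rule"].mean()),
                    "n": n,
                }
            )
        import itertools

        for a, b in itertools.combinations(method_names, 2):
            res = stats.compare_adherence(
                flags[a]["meets_tpa_180"].to_numpy(), flags[b]["meets_tpa_180"].to_numpy()
            )
            adh_test_rows.append(
                {
                    "pair": f"{a} - {b}",
                    "n_a_only": res.n_a_only,
                    "n_b_only": res.n_b_only,
                    "p_value": res.p_value,
                }
            )
    elif n == 0:
        logger.info("0 included subjects; report is empty")

    mean_valid_days = (
        float(np.mean([summaries[method_names[0]]["n_valid_days"].mean()])) if n else float("nan")
    )
    return CohortReport(
        methods=method_names,
        n_files=n_files,
        n_parsed=n_parsed,
        n_included=n,
        cohort_mean_weartime_min=cohort_wear,
        mean_valid_days=mean_valid_days,
        table3=table3,
        contrasts=pd.DataFrame(
            contrast_rows,
            columns=["outcome", "pair", "estimate", "se", "t", "p_bonf", "ci_low", "ci_high"],
        ),
        anova=anova,
        adherence=pd.DataFrame(
            adherence_rows, columns=["method", "pct_meets_tpa", "pct_meets_sb_bout_rule", "n"]
        ),
        adherence_tests=pd.DataFrame(
            adh_test_rows, columns=["pair", "n_a_only", "n_b_only", "p_value"]
        ),
        subject_summaries=summaries,
    )
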