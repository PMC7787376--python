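"""End-to-end pipeline steps over file-based inputs.

Each ``cmd_*`` function is a pure function of its configuration, input
files and seed: scoring produces the analysis table and match ledger,
comparison produces the paired-test report plus the radar-plot matrix,
and modelling produces the hierarchical-regression report.  Outputs are
delimited UTF-8 tables so nothing downstream depends on graphics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imputation import impute, pool
from .inference import bonferroni_alpha, hier_regression, paired_t
from .lexicon import DIMENSIONS, INTUITIVE, Lexicon, Orientation, load_lexicon
from .matcher import read_word_map
from .scoring import (
    Activity,
    DEMOGRAPHIC_COLUMNS,
    build_analysis_table,
    score_column,
)

__all__ = ["RunConfig", "cmd_score", "cmd_compare", "cmd_model", "radar_matrix"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and settings for a pipeline run."""

    lexicon_path: str | Path
    responses_path: str | Path
    demographics_path: str | Path
    alias_map_path: str | Path | None = None
    spelling_map_path: str | Path | None = None
    lexicon_orientation: Orientation = INTUITIVE
    lexicon_column_map: Mapping[str, str] | None = None
    min_words: int = 1
    mode: str = "multiple-imputation"  # "multiple-imputation" | "complete-case"
    m: int = 20
    iterations: int = 10
    seed: int | None = None
    alpha: float = 0.05
    k_comparisons: int = 3

    def __post_init__(self) -> None:
        if self.mode not in {"multiple-imputation", "complete-case"}:
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.mode == "multiple-imputation" and self.seed is None:
            raise ValueError("a seed is required in multiple-imputation mode")

    def load_lexicon(self) -> Lexicon:
        return load_lexicon(
            self.lexicon_path,
            column_map=self.lexicon_column_map,
            orientation=self.lexicon_orientation,
        )

    def load_maps(self) -> tuple[dict, dict]:
        alias = read_word_map(self.alias_map_path) if self.alias_map_path else {}
        spelling = read_word_map(self.spelling_map_path) if self.spelling_map_path else {}
        return alias, spelling


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, encoding="utf-8", keep_default_na=True)


def cmd_score(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a response file: returns (analysis table, match ledger table)."""
    lex = config.load_lexicon()
    alias, spelling = config.load_maps()
    responses = _read_table(config.responses_path)
    demographics = _read_table(config.demographics_path)
    from .matcher import match_table

    _, ledger = match_table(responses, lex, alias_map=alias, spelling_map=spelling)
    table = build_analysis_table(
        responses, demographics, lex,
        min_words=config.min_words, alias_map=alias, spelling_map=spelling,
    )
    return table, ledger.to_frame()


def radar_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """3 activities x 3 dimensions matrix of mean scores (radar-plot data)."""
    rows = {}
    for act in Activity:
        rows[act.value] = {
            dim: float(table[score_column(dim, act)].mean(skipna=True))
            for dim in DIMENSIONS
        }
    return pd.DataFrame(rows).T[list(DIMENSIONS)]


def _paired_report(
    tables: Sequence[pd.DataFrame],
    pairs: Mapping[str, tuple[str, str]],
    alpha_per_test: float,
) -> pd.DataFrame:
    """Paired-test table over one (complete-case) or m (imputed) copies."""
    rows = []
    for label, (col_a, col_b) in pairs.items():
        if len(tables) == 1:
            res = paired_t(tables[0][col_a], tables[0][col_b])
            row = {
                "comparison": label, "n": res.n_pairs,
                "mean_a": res.mean_a, "mean_b": res.mean_b,
                "mean_diff": res.mean_diff, "se": res.se_diff,
                "ci_low": res.ci[0], "ci_high": res.ci[1],
                "t": res.t, "df": res.df, "p": res.p, "cohen_d": res.cohen_d,
            }
        else:
            per = [paired_t(t[col_a], t[col_b]) for t in tables]
            pooled = pool(
                [r.mean_diff for r in per], [r.se_diff for r in per],
                df_com=per[0].df,
            )
            row = {
                "comparison": label, "n": per[0].n_pairs,
                "mean_a": float(np.mean([r.mean_a for r in per])),
                "mean_b": float(np.mean([r.mean_b for r in per])),
                "mean_diff": pooled.estimate, "se": pooled.se,
                "ci_low": pooled.ci[0], "ci_high": pooled.ci[1],
                "t": pooled.estimate / pooled.se if pooled.se > 0 else np.nan,
                "df": pooled.df, "p": pooled.p,
                "cohen_d": float(np.mean([r.cohen_d for r in per])),
            }
        row["significant"] = bool(row["p"] < alpha_per_test) if np.isfinite(row["p"]) else False
        rows.append(row)
    return pd.DataFrame(rows)


def _completed_tables(table: pd.DataFrame, config: RunConfig) -> list[pd.DataFrame]:
    if config.mode == "complete-case":
        return [table]
    imp = impute(table, m=config.m, iterations=config.iterations, seed=config.seed)
    return list(imp.tables)


def cmd_compare(table: pd.DataFrame, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Self-vs-others and pre-post paired comparisons, plus radar data.

    In multiple-imputation mode the table is imputed (m copies) and each
    comparison is pooled by Rubin's rules; in complete-case mode pairs
    with a missing member are dropped test-wise.  Significance is
    flagged at the Bonferroni-adjusted level alpha/k at full precision.
    """
    alpha_per_test = bonferroni_alpha(config.alpha, config.k_comparisons)
    tables = _completed_tables(table, config)

    self_vs_other = {
        f"{dim}: self vs others (baseline)": (
            score_column(dim, Activity.SELF_T1), score_column(dim, Activity.OTHER_T1)
        )
        for dim in DIMENSIONS
    }
    pre_post = {
        f"{dim}: course-end vs baseline (self)": (
            score_column(dim, Activity.SELF_T2), score_column(dim, Activity.SELF_T1)
        )
        for dim in DIMENSIONS
    }
    return {
        "self_vs_other": _paired_report(tables, self_vs_other, alpha_per_test),
        "pre_post": _paired_report(tables, pre_post, alpha_per_test),
        "radar": radar_matrix(table),
    }


def cmd_model(table: pd.DataFrame, config: RunConfig) -> dict[str, dict]:
    """Hierarchical regressions of course-end scores on demographics.

    For each dimension: block 1 is the baseline score, block 2 the
    socio-demographic predictors.  Coefficients are pooled across the m
    imputed copies (Rubin's rules); model-fit statistics, which have no
    pooling rule, are reported as min-max ranges over the copies.  In
    complete-case mode the ranges collapse to a point.
    """
    predictors = [c for c in DEMOGRAPHIC_COLUMNS]
    tables = _completed_tables(table, config)

    out: dict[str, dict] = {}
    for dim in DIMENSIONS:
        outcome = score_column(dim, Activity.SELF_T2)
        baseline = score_column(dim, Activity.SELF_T1)
        fits = [
            hier_regression(t, outcome, block1=[baseline], block2=predictors)
            for t in tables
        ]
        coef_names = fits[0].coefficients.index
        pooled_coef = {}
        for name in coef_names:
            ests = [f.coefficients.loc[name, "estimate"] for f in fits]
            ses = [f.coefficients.loc[name, "se"] for f in fits]
            if len(fits) == 1:
                row = fits[0].coefficients.loc[name]
                pooled_coef[name] = {
                    "estimate": row["estimate"], "se": row["se"],
                    "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "p": row["p"], "semipartial": row["semipartial"],
                }
            else:
                pe = pool(ests, ses, df_com=fits[0].block2.df_resid)
                pooled_coef[name] = {
                    "estimate": pe.estimate, "se": pe.se,
                    "ci_low": pe.ci[0], "ci_high": pe.ci[1], "p": pe.p,
                    "semipartial": float(
                        np.mean([f.coefficients.loc[name, "semipartial"] for f in fits])
                    ),
                }
        ranges = pd.DataFrame(
            {
                "r2_block1": [f.block1.r2 for f in fits],
                "f_block1": [f.block1.f for f in fits],
                "r2_full": [f.block2.r2 for f in fits],
                "f_full": [f.block2.f for f in fits],
                "delta_r2": [f.delta_r2 for f in fits],
                "delta_f": [f.delta_f for f in fits],
            }
        ).agg(["min", "max"]).T
        out[dim] = {
            "coefficients": pd.DataFrame(pooled_coef).T,
            "fit_ranges": ranges,
        }
    return out
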