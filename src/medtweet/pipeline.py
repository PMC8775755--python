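"""One-call pipeline: ingest or generate a corpus, run every analysis stage,
and write the result surfaces (summary table, OR panels, sentiment, reach,
trends, seasonality) as TSV/JSON files."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .categorize import (
    CategoryScheme,
    DEFAULT_SCHEME,
    FilterConfig,
    apply_filters,
    assign_categories,
)
from .corpus_io import read_corpus, read_followers, read_lexicon, write_corpus
from .engagement import (
    engagement_odds_ratio,
    or_panel,
    round_half_up,
    summarize_categories,
)
from .reach import potential_reach
from .sentiment import classify_sentiment, score_category
from .synthetic_data import (
    GeneratorConfig,
    MINI_LEXICON,
    generate_corpus,
    make_follower_table,
)
from .temporal import TimeBinSpec, aggregate_counts, monthly_seasonality_test, period_proportions

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run.

    Exactly one of ``corpus_path`` and ``generator`` must be set. When the
    corpus is generated, the bundled mini-lexicon and the synthetic
    follower table stand in for the lexicon/followers files unless paths
    are given explicitly. Reach and sentiment are skipped (with a log
    notice) when their inputs are absent for a file-based corpus.
    """

    corpus_path: str | None = None
    generator: GeneratorConfig | None = None
    scheme: CategoryScheme = DEFAULT_SCHEME
    filters: FilterConfig = field(default_factory=FilterConfig)
    lexicon_path: str | None = None
    followers_path: str | None = None
    panel_reference: str = "soft_drinks"
    contrast_category: str = "mediterranean_diet"
    contrast_reference: str = "dairy"
    output_dir: str = "medtweet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.corpus_path is None) == (self.generator is None):
            raise ValueError(
                "exactly one of corpus_path and generator must be set"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML or JSON run configuration."""
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw) or {}
        return cls.from_dict(data, **overrides)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any], **overrides: Any) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        seed = overrides.get("seed", data.get("seed", 0))
        kwargs["seed"] = int(seed)
        if "corpus" in data:
            kwargs["corpus_path"] = str(data["corpus"])
        if "generator" in data:
            gen = dict(data["generator"] or {})
            gen.setdefault("seed", kwargs["seed"])
            kwargs["generator"] = _generator_from_dict(gen)
        if "corpus" not in data and "generator" not in data:
            kwargs["generator"] = GeneratorConfig(seed=kwargs["seed"])
        if "scheme" in data:
            kwargs["scheme"] = CategoryScheme.from_mapping(data["scheme"])
        if "filters" in data:
            kwargs["filters"] = _filters_from_dict(data["filters"])
        for key in (
            "lexicon_path",
            "followers_path",
            "panel_reference",
            "contrast_category",
            "contrast_reference",
            "output_dir",
        ):
            if key in data:
                kwargs[key] = data[key]
        kwargs.update(
            {k: v for k, v in overrides.items() if k != "seed" and v is not None}
        )
        cfg = cls(**kwargs)
        if cfg.generator is not None and cfg.generator.seed != cfg.seed:
            cfg = replace(cfg, generator=replace(cfg.generator, seed=cfg.seed))
        return cfg


def _generator_from_dict(data: Mapping[str, Any]) -> GeneratorConfig:
    from .synthetic_data import CategoryTarget, DEFAULT_TARGETS

    kwargs: dict[str, Any] = {"seed": int(data.get("seed", 0))}
    if "targets" in data:
        kwargs["targets"] = {
            cat: CategoryTarget(*vals) if not isinstance(vals, CategoryTarget) else vals
            for cat, vals in data["targets"].items()
        }
    for key in ("date_start", "date_end"):
        if key in data:
            kwargs[key] = date.fromisoformat(str(data[key]))
    for key in (
        "date_distribution",
        "yearly_weights",
        "sentiment_targets",
        "default_sentiment",
        "language",
        "multi_category_rate",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "accounts" in data:
        kwargs["accounts"] = tuple(data["accounts"])
    return GeneratorConfig(**kwargs)


def _filters_from_dict(data: Mapping[str, Any]) -> FilterConfig:
    kwargs: dict[str, Any] = {}
    for key in ("date_start", "date_end"):
        if key in data:
            kwargs[key] = None if data[key] is None else date.fromisoformat(str(data[key]))
    if "allowed_accounts" in data and data["allowed_accounts"] is not None:
        kwargs["allowed_accounts"] = frozenset(data["allowed_accounts"])
    for key in (
        "required_language",
        "require_relevant",
        "drop_hashtag_only",
        "drop_picture_only",
    ):
        if key in data:
            kwargs[key] = data[key]
    return FilterConfig(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _summary_frame(rows, totals) -> pd.DataFrame:
    records = []
    for s in list(rows) + [totals]:
        cat, n, pct, likes, lpt, rts, rpt = s.rounded()
        records.append(
            {
                "category": cat,
                "n_tweets": n,
                "pct_tweets": pct,
                "n_likes": likes,
                "likes_per_tweet": "" if lpt is None else lpt,
                "n_retweets": rts,
                "retweets_per_tweet": "" if rpt is None else rpt,
            }
        )
    # the totals row reports no per-tweet ratios, matching the table layout
    records[-1]["likes_per_tweet"] = ""
    records[-1]["retweets_per_tweet"] = ""
    return pd.DataFrame.from_records(records)


def _panel_frame(panel) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "category": r.category,
                "reference": r.reference,
                "measure": r.measure,
                "odds_ratio": r.rounded()[0],
                "ci_low": r.rounded()[1],
                "ci_high": r.rounded()[2],
            }
            for r in panel
        ]
    )


def _trend_frame(corpus, scheme, spec, as_percent: bool = False) -> pd.DataFrame:
    frames = []
    for measure in ("tweets", "retweets"):
        grid = aggregate_counts(corpus, scheme, spec, measure)
        if as_percent:
            grid = period_proportions(grid).round(1)
        part = grid.reset_index()
        part.insert(1, "measure", measure)
        frames.append(part)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the in-memory results keyed by stage. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:
            logger.error("stage %r failed: %s", name, exc)
            raise PipelineError(name, exc) from exc
        bundle[name] = result
        return result

    # --- ingest -----------------------------------------------------------
    def _ingest():
        if config.generator is not None:
            corpus = generate_corpus(config.generator, config.scheme)
            write_corpus(corpus, outdir / "corpus.jsonl")
            return corpus
        return read_corpus(config.corpus_path)

    corpus = stage("ingest", _ingest)

    # --- filter -----------------------------------------------------------
    def _filter():
        filtered, audit = apply_filters(corpus, config.scheme, config.filters)
        (outdir / "filter_audit.json").write_text(
            json.dumps(
                {"removed": audit.removed, "retained": audit.retained}, indent=2
            )
        )
        return filtered, audit

    filtered, audit = stage("filter", _filter)

    # --- summary table ----------------------------------------------------
    def _summary():
        rows, totals = summarize_categories(filtered, config.scheme)
        _write_tsv(_summary_frame(rows, totals), outdir / "summary_table.tsv")
        return rows, totals

    rows, totals = stage("summary", _summary)

    # --- odds-ratio panels ------------------------------------------------
    def _panels():
        panels = {}
        for measure in ("likes", "retweets"):
            panel = or_panel(rows, config.panel_reference, measure)
            panels[measure] = panel
            _write_tsv(_panel_frame(panel), outdir / f"or_panel_{measure}.tsv")
        by_name = {s.category: s for s in rows}
        contrast = []
        cat = by_name.get(config.contrast_category)
        ref = by_name.get(config.contrast_reference)
        if cat and ref and cat.n_tweets and ref.n_tweets:
            for measure in ("likes", "retweets"):
                ev_c = cat.n_likes if measure == "likes" else cat.n_retweets
                ev_r = ref.n_likes if measure == "likes" else ref.n_retweets
                if ev_c and ev_r:
                    contrast.append(
                        engagement_odds_ratio(
                            ev_c, cat.n_tweets, ev_r, ref.n_tweets,
                            category=cat.category, reference=ref.category,
                            measure=measure,
                        )
                    )
        panels["contrast"] = contrast
        _write_tsv(_panel_frame(contrast), outdir / "or_contrast.tsv")
        return panels

    stage("odds_ratios", _panels)

    # --- sentiment --------------------------------------------------------
    def _sentiment():
        if config.lexicon_path is not None:
            lexicon = read_lexicon(config.lexicon_path)
        elif config.generator is not None:
            lexicon = dict(MINI_LEXICON)
        else:
            logger.info("sentiment skipped: no lexicon supplied")
            return None
        records = []
        scores = {}
        for name in config.scheme.names:
            members = [
                t for t in filtered if name in assign_categories(t, config.scheme)
            ]
            if not members:
                continue
            mean = score_category(members, lexicon)
            scores[name] = mean
            records.append(
                {
                    "category": name,
                    "mean_score": round_half_up(mean, 1),
                    "classification": classify_sentiment(mean).value,
                }
            )
        _write_tsv(pd.DataFrame.from_records(records), outdir / "sentiment.tsv")
        return scores

    stage("sentiment", _sentiment)

    # --- reach ------------------------------------------------------------
    def _reach():
        if config.followers_path is not None:
            followers = read_followers(config.followers_path)
        elif config.generator is not None:
            followers = make_follower_table(config.generator)
        else:
            logger.info("reach skipped: no follower table supplied")
            return None
        records = []
        reaches = {}
        for name in config.scheme.names:
            members = [
                t for t in filtered if name in assign_categories(t, config.scheme)
            ]
            value = potential_reach(members, followers)
            reaches[name] = value
            records.append(
                {
                    "category": name,
                    "reach": value,
                    "reach_millions": round_half_up(value / 1e6, 1),
                }
            )
        _write_tsv(pd.DataFrame.from_records(records), outdir / "reach.tsv")
        return reaches

    stage("reach", _reach)

    # --- temporal trends --------------------------------------------------
    window = config.filters
    year_start = (window.date_start or date(2009, 1, 1)).year
    year_end = (window.date_end or date(2019, 12, 31)).year

    def _trends():
        yearly = TimeBinSpec("year", year_start, year_end)
        monthly = TimeBinSpec("month_of_year", year_start, year_end)
        periods = TimeBinSpec("custom_periods", year_start, year_end)
        out = {
            "yearly": _trend_frame(filtered, config.scheme, yearly),
            "monthly": _trend_frame(filtered, config.scheme, monthly),
            "periods": _trend_frame(filtered, config.scheme, periods, as_percent=True),
        }
        _write_tsv(out["yearly"], outdir / "trends_yearly.tsv")
        _write_tsv(out["monthly"], outdir / "trends_monthly.tsv")
        _write_tsv(out["periods"], outdir / "trends_periods.tsv")
        return out

    stage("trends", _trends)

    # --- seasonality ------------------------------------------------------
    def _seasonality():
        results = {}
        for measure in ("tweets", "retweets"):
            res = monthly_seasonality_test(filtered, measure, config.scheme)
            results[measure] = {
                "H": res.H,
                "df": res.df,
                "p_value": res.p_value,
                "group_sizes": list(res.group_sizes),
            }
        (outdir / "seasonality.json").write_text(json.dumps(results, indent=2))
        return results

    stage("seasonality", _seasonality)

    # --- run log ----------------------------------------------------------
    def _log():
        echo = {
            "medtweet_version": __version__,
            "seed": config.seed,
            "input": config.corpus_path or "generated",
            "scheme": config.scheme.to_mapping(),
            "filters": {
                k: (str(v) if isinstance(v, date) else sorted(v) if isinstance(v, frozenset) else v)
                for k, v in asdict(config.filters).items()
            },
            "panel_reference": config.panel_reference,
            "contrast": [config.contrast_category, config.contrast_reference],
            "retained": audit.retained,
        }
        (outdir / "run_log.json").write_text(json.dumps(echo, indent=2))
        return echo

    stage("run_log", _log)
    return bundle
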