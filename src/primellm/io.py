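"""Delimited-table I/O, run configuration and the end-to-end report.

All tables are plain TSV (CSV accepted) so they stay hand-editable.
Multi-valued cells (option sets) are ";"-joined; ";" is therefore forbidden
inside option codes and this is enforced on read.  Validation failures
report the offending row number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import grading, metric, stats, synthetic
from .errors import ValidationError
from .grading import DOMAINS, GRADED_COLUMNS, AnswerKey

logger = logging.getLogger(__name__)

KEY_COLUMNS = (
    "question_id", "vignette_id", "domain", "options", "correct",
    "requires_image", "age_group", "sex",
)
RESPONSE_COLUMNS = ("model_id", "question_id", "replicate", "selected")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _split_cell(cell) -> frozenset:
    if pd.isna(cell) or str(cell).strip() == "":
        return frozenset()
    return frozenset(tok.strip() for tok in str(cell).split(";") if tok.strip())


def _join_cell(values: Iterable[str]) -> str:
    vals = sorted(map(str, values))
    for v in vals:
        if ";" in v:
            raise ValidationError(f"option code {v!r} contains the reserved ';' separator")
    return ";".join(vals)


def _parse_bool(cell) -> bool:
    return str(cell).strip().lower() in ("1", "true", "yes")


# --------------------------------------------------------------------------
# answer keys


def write_keys(keys: Iterable[AnswerKey], path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    rows = [
        (
            k.question_id, k.vignette_id, k.domain, _join_cell(k.options),
            _join_cell(k.correct), k.requires_image, k.age_group, k.sex,
        )
        for k in keys
    ]
    pd.DataFrame(rows, columns=list(KEY_COLUMNS)).to_csv(
        path, sep=_sep_for(path, sep), index=False
    )


def read_keys(path: str | Path, sep: str | None = None) -> list[AnswerKey]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    keys = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 is the header
        if row.domain not in DOMAINS:
            raise ValidationError(
                f"{path}, row {i}: unknown domain {row.domain!r} for question {row.question_id!r}"
            )
        if row.question_id in seen:
            raise ValidationError(f"{path}, row {i}: duplicate question_id {row.question_id!r}")
        seen.add(row.question_id)
        try:
            keys.append(
                AnswerKey(
                    question_id=row.question_id,
                    vignette_id=row.vignette_id,
                    domain=row.domain,
                    options=_split_cell(row.options),
                    correct=_split_cell(row.correct),
                    requires_image=_parse_bool(row.requires_image),
                    age_group=row.age_group,
                    sex=row.sex,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return keys


# --------------------------------------------------------------------------
# responses / graded tables


def write_responses(responses: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    out = responses.copy()
    out["selected"] = out["selected"].map(_join_cell)
    out.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_responses(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a response table.  If a ``score`` column is present the table is
    pre-graded and returned as such (grading is bypassed downstream)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    pregraded = "score" in df.columns
    needed = ("model_id", "question_id", "replicate", "score" if pregraded else "selected")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer replicate index ({exc})") from exc
    if pregraded:
        df["score"] = df["score"].astype(int)
        if not df["score"].isin((0, 1)).all():
            bad = df.index[~df["score"].isin((0, 1))][0] + 2
            raise ValidationError(f"{path}, row {bad}: score must be 0 or 1")
    else:
        df["selected"] = df["selected"].map(_split_cell)
    return df


def graded_from_scores(
    scores: pd.DataFrame,
    keys: Iterable[AnswerKey] | Mapping[str, AnswerKey],
    multimodal_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """Build a graded table from pre-assigned 0/1 scores (grading bypassed)."""
    key_map = keys if isinstance(keys, Mapping) else grading.index_keys(keys)
    orphans = sorted(set(scores["question_id"]) - set(key_map))
    if orphans:
        raise ValidationError(f"pre-graded rows reference unknown question_ids: {orphans}")
    rows = []
    for rec in scores.itertuples(index=False):
        key = key_map[rec.question_id]
        excluded = key.requires_image and not bool(multimodal_flags.get(rec.model_id, False))
        rows.append(
            (rec.model_id, rec.question_id, key.vignette_id, key.domain,
             int(rec.replicate), pd.NA if excluded else int(rec.score), excluded,
             key.age_group, key.sex)
        )
    out = pd.DataFrame(rows, columns=list(GRADED_COLUMNS))
    out["score"] = out["score"].astype("Int64")
    return out


def write_graded(graded: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    graded[list(GRADED_COLUMNS)].to_csv(path, sep=_sep_for(path, sep), index=False)


def read_graded(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    missing = [c for c in GRADED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    df["replicate"] = df["replicate"].astype(int)
    df["excluded"] = df["excluded"].map(_parse_bool)
    df["score"] = pd.array(
        [pd.NA if s == "" else int(s) for s in df["score"]], dtype="Int64"
    )
    return df[list(GRADED_COLUMNS)]


def read_model_flags(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    missing = [c for c in ("model_id", "reasoning", "multimodal") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    df["reasoning"] = df["reasoning"].map(_parse_bool)
    df["multimodal"] = df["multimodal"].map(_parse_bool)
    return df


# --------------------------------------------------------------------------
# run configuration & report


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    domain_order: tuple = metric.CANONICAL_ORDER
    aggregation_mode: str = "vignette_then_mean"
    alpha: float = 0.05
    variance_mode: str = "welch"
    domain_reference: str = "DT"
    keys_path: str | None = None
    responses_path: str | None = None
    model_flags_path: str | None = None
    output_dir: str = "primellm_report"
    seed: int = 1
    synthetic: bool = False  # generate inputs with the default synthetic benchmark
    synthetic_overrides: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def __post_init__(self) -> None:
        self.domain_order = tuple(self.domain_order)
        if len(self.domain_order) < 3 or len(set(self.domain_order)) != len(self.domain_order):
            raise ValidationError("domain_order must be >= 3 distinct labels")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_report(config: RunConfig) -> dict:
    """Run the pipeline end to end and write a report bundle.

    Stages: load or simulate inputs -> grade -> domain accuracies ->
    PrIME scores -> between-subjects ANOVA + Tukey HSD -> reasoning
    contrast with effect sizes -> OLS on model-level scores -> mixed model
    on question-level accuracy -> failure rates -> radar figure.
    Returns the manifest (artifact -> sha256) and writes it alongside a log.
    """
    from .plotting import render_radar  # deferred: matplotlib import cost

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        if config.synthetic:
            gen = synthetic.default_config(seed=config.seed, **config.synthetic_overrides)
            keys, responses, truth = synthetic.generate_benchmark(gen)
            flags = synthetic.model_flags_frame(gen)
            (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        else:
            keys = read_keys(config.keys_path)
            responses = read_responses(config.responses_path)
            flags = read_model_flags(config.model_flags_path)
        multimodal = dict(zip(flags["model_id"], flags["multimodal"]))
        reasoning = dict(zip(flags["model_id"], flags["reasoning"]))

        stage = "grade"
        if "score" in responses.columns:
            graded = graded_from_scores(responses, keys, multimodal)
        else:
            graded = grading.grade_benchmark(responses, keys, multimodal)
        write_graded(graded, outdir / "graded.tsv")

        stage = "score"
        dom_acc = grading.domain_accuracy(graded, mode=config.aggregation_mode)
        scores, summary = metric.prime_table(dom_acc, domain_order=config.domain_order)
        q_acc = grading.question_accuracy(graded)
        overall = metric.overall_accuracy(q_acc)
        scores.to_csv(outdir / "prime_scores.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "prime_summary.tsv", sep="\t", index=False)
        overall.to_csv(outdir / "overall_accuracy.tsv", sep="\t", index=False)

        stage = "compare"
        groups, labels = [], []
        for m, grp in scores.groupby("model_id"):
            labels.append(m)
            groups.append(grp["prime_score"].to_numpy())
        results: dict = {}
        if len(groups) >= 2 and min(len(g) for g in groups) >= 2:
            anova = stats.oneway_anova(groups)
            tukey = stats.tukey_hsd(groups, labels=labels, alpha=config.alpha)
            tukey.frame.assign(
                significant=tukey.frame["p_adjusted"] < config.alpha
            ).to_csv(outdir / "tukey_pairwise.tsv", sep="\t", index=False)
            results["prime_anova"] = {
                "F": anova.F, "df": [anova.df_num, anova.df_den], "p": anova.p,
            }
        merged = summary.assign(reasoning=summary["model_id"].map(reasoning))
        a = merged.loc[merged["reasoning"].astype(bool), "mean"].to_numpy()
        b = merged.loc[~merged["reasoning"].astype(bool), "mean"].to_numpy()
        if a.size >= 2 and b.size >= 2:
            ttest, effects = stats.two_sample(a, b, variance_mode=config.variance_mode)
            results["reasoning_contrast"] = {
                "t": ttest.t, "df": ttest.df, "p": ttest.p,
                "variance_mode": ttest.variance_mode,
                "d": effects.d, "g": effects.g, "g_ci": list(effects.g_ci),
                "cles": effects.cles,
            }
        rho, p_rho = stats.spearman_corr(
            merged.sort_values("model_id")["mean"],
            overall.sort_values("model_id")["mean"],
        )
        results["prime_vs_accuracy_spearman"] = {"rho": rho, "p": p_rho}

        stage = "regress"
        model_level = scores.assign(reasoning=scores["model_id"].map(reasoning).astype(bool))
        ols = stats.ols_model(model_level, response="prime_score", predictors=("reasoning",))
        key_meta = pd.DataFrame(
            [(k.question_id, k.domain, k.age_group, k.sex) for k in keys],
            columns=["question_id", "domain", "age_group", "sex"],
        )
        q_level = q_acc.merge(key_meta, on="question_id")
        q_level["reasoning"] = q_level["model_id"].map(reasoning).astype(bool)
        mixed = stats.mixed_linear(q_level, domain_reference=config.domain_reference)
        results["ols_model_level"] = {
            "coefficients": {t: list(v) for t, v in ols.coefficients.items()},
            "r_squared": ols.r_squared,
        }
        results["mixed_question_level"] = {
            "coefficients": {t: list(v) for t, v in mixed.coefficients.items()},
            "random_intercept_variance": mixed.random_intercept_variance,
            "singular": mixed.singular,
        }
        results["alpha"] = config.alpha
        (outdir / "stats.json").write_text(json.dumps(results, indent=2, sort_keys=True))

        stage = "failure-rates"
        for name, keys_by in (
            ("by_model_domain", ["model_id", "domain"]),
            ("by_age_domain", ["age_group", "domain"]),
            ("by_sex_domain", ["sex", "domain"]),
        ):
            grading.failure_rates(graded, keys_by).to_csv(
                outdir / f"failure_{name}.tsv", sep="\t", index=False
            )

        stage = "figures"
        mean_profiles = []
        prof_labels = []
        mean_acc = dom_acc.groupby(["model_id", "domain"])["accuracy"].mean().unstack()
        for m in list(mean_acc.index)[:6]:
            mean_profiles.append(
                metric.DomainProfile(
                    tuple(mean_acc.loc[m, list(config.domain_order)]),
                    config.domain_order,
                )
            )
            prof_labels.append(m)
        render_radar(mean_profiles, outdir / "radar.svg", labels=prof_labels)
    except Exception as exc:
        raise type(exc)(f"report stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("report written to %s (%d artifacts)", outdir, len(manifest["artifacts"]))
    return manifest
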