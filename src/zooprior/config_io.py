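"""Prioritization configuration, tabular inputs and report output.

A prioritization run is driven by three plain-text inputs:

``config.yaml``
    The criteria (each with exactly one categorical question and its
    answer scale), the disease list, and free-text metadata.
``judgments/<participant>.csv`` (or one combined CSV)
    Per-participant pairwise comparisons, columns
    ``criterion_a, criterion_b, ratio``.
``answers.csv``
    One row per disease, one column per criterion id, cells holding the
    category label answered for that criterion's question.

Answer scales are categorical and ordinal: *binomial* scales have exactly
two categories, one of which (``full_score_category``) scores 1 and the
other 0; *multinomial* scales have 2-5 ordered categories listed from
lowest to highest, scored by ordinal position.

Validation is total: every violation found in a file is reported in a
single :class:`~zooprior.errors.ValidationError`.  Hard rules (at least 2
criteria, unique ids, labels within scales, complete pairwise sets) always
error; the guidance bands (5-9 criteria, 15-30 diseases, 6-12
participants, at most 5 categories) warn by default and error under
``strict``.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ahp
from .errors import RecommendationWarning, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Criterion",
    "AnswerScale",
    "Question",
    "PrioritizationConfig",
    "AnswerTable",
    "load_config",
    "save_config",
    "example_criteria_library",
    "load_answers",
    "load_judgments",
    "write_report",
]

SCALE_KINDS = ("binomial", "multinomial")


@dataclass(frozen=True)
class Criterion:
    """One agreed criterion defining what makes a zoonosis important."""

    id: str
    label: str
    description: str | None = None


@dataclass(frozen=True)
class AnswerScale:
    """Ordered categorical answer scale for one question.

    ``categories`` are listed lowest-first; for binomial scales
    ``full_score_category`` names the answer that scores 1.
    """

    kind: str
    categories: tuple[str, ...]
    full_score_category: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def lowest_category(self) -> str:
        """The category with the smallest score contribution."""
        if self.kind == "binomial":
            other = [c for c in self.categories if c != self.full_score_category]
            return other[0]
        return self.categories[0]


@dataclass(frozen=True)
class Question:
    """The single categorical question measuring one criterion."""

    criterion_id: str
    text: str
    scale: AnswerScale
    source_note: str | None = None


@dataclass(frozen=True)
class PrioritizationConfig:
    """A complete prioritization setup: criteria, questions, diseases."""

    criteria: tuple[Criterion, ...]
    questions: tuple[Question, ...]
    diseases: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "questions", tuple(self.questions))
        object.__setattr__(self, "diseases", tuple(str(d) for d in self.diseases))
        errors = _validate_config(self)
        if errors:
            raise ValidationError(errors)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def question_for(self, criterion_id: str) -> Question:
        for q in self.questions:
            if q.criterion_id == criterion_id:
                return q
        raise KeyError(criterion_id)

    def recommendation_notes(self, n_participants: int | None = None) -> list[str]:
        """Guidance-band violations (empty when everything is in range)."""
        notes = []
        nc = len(self.criteria)
        if not 5 <= nc <= 9:
            notes.append(f"{nc} criteria; 5-9 are recommended for reliable AHP ranking")
        nd = len(self.diseases)
        if not 15 <= nd <= 30:
            notes.append(f"{nd} diseases; about 15-30 are recommended")
        for q in self.questions:
            if len(q.scale.categories) > 5:
                notes.append(
                    f"question for {q.criterion_id!r} has "
                    f"{len(q.scale.categories)} categories; at most 5 are recommended"
                )
        if n_participants is not None and not 6 <= n_participants <= 12:
            notes.append(
                f"{n_participants} participants; 6-12 are recommended to balance "
                "variation in opinion with a manageable group size"
            )
        return notes


def _validate_scale(scale: AnswerScale, where: str) -> list[str]:
    errors = []
    if scale.kind not in SCALE_KINDS:
        errors.append(f"{where}: unknown answer-scale kind {scale.kind!r}")
        return errors
    cats = scale.categories
    if len(set(cats)) != len(cats):
        errors.append(f"{where}: duplicate category labels {list(cats)}")
    if any(not str(c).strip() for c in cats):
        errors.append(f"{where}: empty category label")
    if scale.kind == "binomial":
        if len(cats) != 2:
            errors.append(
                f"{where}: binomial scale must have exactly 2 categories, "
                f"got {len(cats)}"
            )
        if scale.full_score_category is None:
            errors.append(f"{where}: binomial scale requires full_score_category")
        elif scale.full_score_category not in cats:
            errors.append(
                f"{where}: full_score_category {scale.full_score_category!r} "
                f"is not one of {list(cats)}"
            )
    else:
        if len(cats) < 2:
            errors.append(
                f"{where}: multinomial scale needs at least 2 ordered "
                f"categories, got {len(cats)}"
            )
        if scale.full_score_category is not None:
            errors.append(
                f"{where}: full_score_category is only valid for binomial scales"
            )
    return errors


def _validate_config(cfg: PrioritizationConfig) -> list[str]:
    errors = []
    ids = [c.id for c in cfg.criteria]
    if len(cfg.criteria) < 2:
        errors.append(f"at least 2 criteria are required, got {len(cfg.criteria)}")
    for c in cfg.criteria:
        if not c.id or not str(c.id).strip():
            errors.append(f"criterion with empty id (label {c.label!r})")
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        errors.append(f"duplicate criterion ids: {sorted(dup)}")
    qids = [q.criterion_id for q in cfg.questions]
    for cid in ids:
        n = qids.count(cid)
        if n != 1:
            errors.append(
                f"criterion {cid!r} must have exactly one question, found {n}"
            )
    for cid in qids:
        if cid not in ids:
            errors.append(f"question refers to unknown criterion {cid!r}")
    for q in cfg.questions:
        errors.extend(_validate_scale(q.scale, f"question for {q.criterion_id!r}"))
    dup_d = {d for d in cfg.diseases if list(cfg.diseases).count(d) > 1}
    if dup_d:
        errors.append(f"duplicate disease names: {sorted(dup_d)}")
    return errors


@dataclass(frozen=True)
class AnswerTable:
    """Disease-by-question categorical answers, validated against a config."""

    rows: dict  # disease -> {criterion_id -> category label}

    def get(self, disease: str, criterion_id: str) -> str:
        return self.rows[disease][criterion_id]

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.rows)


def _apply_recommendations(notes: list[str], strict: bool) -> None:
    if not notes:
        return
    if strict:
        raise ValidationError([f"(strict) {n}" for n in notes])
    for n in notes:
        warnings.warn(n, RecommendationWarning)


# ---------------------------------------------------------------------------
# YAML configuration


def load_config(path, strict: bool = False) -> PrioritizationConfig:
    """Read and validate a ``config.yaml`` prioritization configuration.

    All scalars are read as strings (so bare ``yes``/``no`` category labels
    survive YAML's boolean rules).  Guidance-band violations warn, or error
    when ``strict`` is true.
    """
    path = Path(path)
    with open(path) as fh:
        # BaseLoader: every scalar is a string; no yes/no -> bool coercion
        raw = yaml.load(fh, Loader=yaml.BaseLoader)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return config_from_dict(raw, strict=strict, where=str(path))


def config_from_dict(
    raw: dict, strict: bool = False, where: str = "config"
) -> PrioritizationConfig:
    """Build a validated configuration from an already-parsed mapping."""
    errors = []
    criteria = []
    questions = []
    for entry in raw.get("criteria", []) or []:
        if not isinstance(entry, dict):
            errors.append(f"{where}: criterion entry {entry!r} is not a mapping")
            continue
        cid = str(entry.get("id", "") or "")
        criteria.append(
            Criterion(
                id=cid,
                label=str(entry.get("label", cid) or cid),
                description=entry.get("description"),
            )
        )
        scale_raw = entry.get("scale") or {}
        if not isinstance(scale_raw, dict):
            errors.append(f"{where}: scale for {cid!r} is not a mapping")
            scale_raw = {}
        scale = AnswerScale(
            kind=str(scale_raw.get("kind", "") or ""),
            categories=tuple(str(c) for c in scale_raw.get("categories", []) or []),
            full_score_category=(
                None
                if scale_raw.get("full_score_category") is None
                else str(scale_raw["full_score_category"])
            ),
        )
        questions.append(
            Question(
                criterion_id=cid,
                text=str(entry.get("question", "") or ""),
                scale=scale,
                source_note=entry.get("source"),
            )
        )
    diseases = tuple(str(d) for d in raw.get("diseases", []) or [])
    metadata = raw.get("metadata") or {}
    if errors:
        raise ValidationError(errors)
    cfg = PrioritizationConfig(
        criteria=tuple(criteria),
        questions=tuple(questions),
        diseases=diseases,
        metadata=dict(metadata),
    )
    _apply_recommendations(cfg.recommendation_notes(), strict)
    return cfg


def config_to_dict(cfg: PrioritizationConfig) -> dict:
    return {
        "metadata": dict(cfg.metadata),
        "criteria": [
            {
                "id": c.id,
                "label": c.label,
                **({"description": c.description} if c.description else {}),
                "question": cfg.question_for(c.id).text,
                **(
                    {"source": cfg.question_for(c.id).source_note}
                    if cfg.question_for(c.id).source_note
                    else {}
                ),
                "scale": {
                    "kind": cfg.question_for(c.id).scale.kind,
                    "categories": list(cfg.question_for(c.id).scale.categories),
                    **(
                        {
                            "full_score_category": cfg.question_for(
                                c.id
                            ).scale.full_score_category
                        }
                        if cfg.question_for(c.id).scale.full_score_category
                        else {}
                    ),
                },
            }
            for c in cfg.criteria
        ],
        "diseases": list(cfg.diseases),
    }


def save_config(cfg: PrioritizationConfig, path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            config_to_dict(cfg), fh, sort_keys=False, default_flow_style=False
        )


def example_criteria_library(strict: bool = False) -> PrioritizationConfig:
    """The packaged example criteria/question library.

    Seven criteria commonly used in zoonotic disease prioritization, each
    with one chosen categorical question, plus a sample disease list.
    Intended as a starting point for facilitated groups developing their
    own criteria.
    """
    ref = importlib.resources.files("zooprior") / "data" / "example_criteria.yaml"
    raw = yaml.load(ref.read_text(), Loader=yaml.BaseLoader)
    return config_from_dict(raw, strict=strict, where="example_criteria.yaml")


# ---------------------------------------------------------------------------
# Answer table CSV


def load_answers(
    path, config: PrioritizationConfig, missing_as_lowest: bool = False
) -> AnswerTable:
    """Read and validate ``answers.csv`` against a configuration.

    The first column must be ``disease``; the remaining columns are
    criterion ids.  Every configured disease must appear exactly once and
    every cell must be a label of that question's scale.  Empty cells are
    errors unless ``missing_as_lowest`` is set, in which case they are
    mapped to the scale's lowest-scoring category (logged per cell).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["disease"])
    return answers_from_frame(df, config, missing_as_lowest, where=str(path))


def answers_from_frame(
    df: pd.DataFrame,
    config: PrioritizationConfig,
    missing_as_lowest: bool = False,
    where: str = "answers",
) -> AnswerTable:
    errors = []
    if df.columns.size == 0 or df.columns[0] != "disease":
        errors.append(f"{where}: first column must be 'disease'")
        raise ValidationError(errors)
    cids = config.criterion_ids
    missing_cols = [c for c in cids if c not in df.columns]
    extra_cols = [c for c in df.columns[1:] if c not in cids]
    if missing_cols:
        errors.append(f"{where}: missing columns for criteria {missing_cols}")
    if extra_cols:
        errors.append(f"{where}: unknown columns {extra_cols}")
    table_d = list(df["disease"]) if "disease" in df.columns else []
    dup = sorted({d for d in table_d if table_d.count(d) > 1})
    if dup:
        errors.append(f"{where}: duplicate disease rows: {dup}")
    missing_d = [d for d in config.diseases if d not in table_d]
    if missing_d:
        errors.append(f"{where}: missing rows for diseases: {missing_d}")
    unknown_d = [d for d in table_d if d not in config.diseases]
    if unknown_d:
        errors.append(f"{where}: rows for unknown diseases: {unknown_d}")
    rows: dict[str, dict[str, str]] = {}
    if not missing_cols:
        for _, rec in df.iterrows():
            disease = rec["disease"]
            if disease not in config.diseases:
                continue
            row = {}
            for cid in cids:
                label = str(rec[cid]).strip()
                scale = config.question_for(cid).scale
                if label == "":
                    if missing_as_lowest:
                        label = scale.lowest_category
                        logger.info(
                            "%s: %s/%s missing; filled with lowest category %r",
                            where,
                            disease,
                            cid,
                            label,
                        )
                    else:
                        errors.append(
                            f"{where}: missing answer for disease {disease!r}, "
                            f"question {cid!r}"
                        )
                        continue
                if label not in scale.categories:
                    errors.append(
                        f"{where}: disease {disease!r}, question {cid!r}: "
                        f"label {label!r} is not in scale "
                        f"{list(scale.categories)}"
                    )
                    continue
                row[cid] = label
            rows[disease] = row
    if errors:
        raise ValidationError(errors)
    # preserve configured disease order
    return AnswerTable(rows={d: rows[d] for d in config.diseases})


def answers_to_frame(
    answers: AnswerTable, config: PrioritizationConfig
) -> pd.DataFrame:
    cids = config.criterion_ids
    return pd.DataFrame(
        [
            {"disease": d, **{c: answers.rows[d][c] for c in cids}}
            for d in answers.diseases
        ]
    )


# ---------------------------------------------------------------------------
# Judgment CSVs


def _judgment_from_frame(
    pid: str, df: pd.DataFrame, config: PrioritizationConfig, where: str
) -> ahp.ParticipantJudgment:
    required = {"criterion_a", "criterion_b", "ratio"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{where}: judgment file needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    pairs = [
        (str(r.criterion_a), str(r.criterion_b), r.ratio)
        for r in df.itertuples(index=False)
    ]
    try:
        matrix = ahp.matrix_from_pairs(pairs, config.criterion_ids)
    except ValidationError as exc:
        raise ValidationError([f"{where}: {e}" for e in exc.errors]) from None
    return ahp.ParticipantJudgment(participant_id=pid, matrix=matrix)


def load_judgments(
    path, config: PrioritizationConfig, strict: bool = False
) -> list[ahp.ParticipantJudgment]:
    """Read pairwise judgments for all participants.

    ``path`` may be a directory of ``<participant>.csv`` files or a single
    CSV; a single file may carry a ``participant`` column to hold several
    participants.  Each participant must supply every unordered criterion
    pair exactly once with a positive ratio.
    """
    path = Path(path)
    judgments: list[ahp.ParticipantJudgment] = []
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ValidationError(f"{path}: no judgment CSV files found")
        for f in files:
            df = pd.read_csv(f)
            judgments.append(_judgment_from_frame(f.stem, df, config, str(f)))
    elif path.is_file():
        df = pd.read_csv(path)
        if "participant" in df.columns:
            for pid, grp in df.groupby("participant", sort=True):
                judgments.append(
                    _judgment_from_frame(
                        str(pid), grp, config, f"{path}[{pid}]"
                    )
                )
        else:
            judgments.append(_judgment_from_frame(path.stem, df, config, str(path)))
    else:
        raise ValidationError(f"{path}: judgment path does not exist")
    notes = []
    if not 6 <= len(judgments) <= 12:
        notes.append(
            f"{len(judgments)} participants; 6-12 are recommended to balance "
            "variation in opinion with a manageable group size"
        )
    _apply_recommendations(notes, strict)
    return judgments


def save_judgments(judgments, directory) -> None:
    """Write one ``<participant>.csv`` per judgment into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j in judgments:
        ids = j.matrix.criteria_ids
        rows = []
        for i in range(len(ids)):
            for k in range(i + 1, len(ids)):
                rows.append(
                    {
                        "criterion_a": ids[i],
                        "criterion_b": ids[k],
                        "ratio": repr(float(j.matrix.values[i, k])),
                    }
                )
        pd.DataFrame(rows).to_csv(directory / f"{j.participant_id}.csv", index=False)


# ---------------------------------------------------------------------------
# Ranked report


def _report_frame(ranked, traces) -> pd.DataFrame:
    """Fixed report columns: rank, disease, total_score, normalized_score,
    then one ``q_<criterion_id>`` per criterion in descending-weight
    (tree-node) order."""
    by_disease = {t.disease: t for t in traces}
    missing = [e.disease for e in ranked.entries if e.disease not in by_disease]
    if missing:
        raise ValidationError(
            f"traces missing for ranked diseases: {missing}"
        )
    crit_order = [e.criterion_id for e in traces[0].entries]
    rows = []
    for e in ranked.entries:
        t = by_disease[e.disease]
        qs = {f"q_{en.criterion_id}": en.weighted_score for en in t.entries}
        rows.append(
            {
                "rank": e.rank,
                "disease": e.disease,
                "total_score": e.total,
                "normalized_score": e.normalized,
                **{f"q_{c}": qs[f"q_{c}"] for c in crit_order},
            }
        )
    return pd.DataFrame(rows)


def write_report(ranked, traces, path, format: str = "csv") -> None:
    """Write the final ranked disease list (with score traces) to disk.

    CSV rounds floating-point scores to 6 decimals; JSON keeps full
    precision and additionally carries the per-question traces; Markdown
    renders the ranked table for pasting into reports.  Output is
    byte-stable given identical inputs.
    """
    path = Path(path)
    df = _report_frame(ranked, traces)
    if format == "csv":
        out = df.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda x: f"{x:.6f}")
        out.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "t_max": ranked.t_max,
            "normalization": ranked.normalization,
            "entries": [
                {
                    "rank": e.rank,
                    "disease": e.disease,
                    "total_score": e.total,
                    "normalized_score": e.normalized,
                }
                for e in ranked.entries
            ],
            "traces": [
                {
                    "disease": t.disease,
                    "total": t.total,
                    "questions": [
                        {
                            "criterion_id": en.criterion_id,
                            "category": en.category_label,
                            "weight": en.weight,
                            "raw_score": en.raw_score,
                            "weighted_score": en.weighted_score,
                        }
                        for en in t.entries
                    ],
                }
                for t in traces
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "markdown":
        cols = list(df.columns)
        lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
        for _, rec in df.iterrows():
            cells = [
                f"{v:.6f}" if isinstance(v, float) else str(v) for v in rec
            ]
            lines.append("| " + " | ".join(cells) + " |")
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(
            f"unknown report format {format!r}: use csv, json or markdown"
        )
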