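"""Seeded generators for every input the prioritization pipeline consumes.

The generator emulates a facilitated prioritization exercise: a panel of
participants who share a latent importance vector ``v`` over the criteria
but express it with multiplicative judgment error, and a disease list
whose categorical answers are drawn from per-question category
probabilities.  Each participant's pairwise matrix is built as

    A[i, j] = (v_i / v_j) * exp(eps),   eps ~ Normal(0, sigma^2)

independently per upper-triangle cell, reciprocals enforced and values
clamped to the Saaty range [1/9, 9] (log-normal multiplicative noise, the
standard judgment-error model in AHP simulation work).  At ``sigma = 0``
every matrix is perfectly consistent and the latent criterion order is
recovered exactly; growing ``sigma`` degrades recovery, which is what the
rank-recovery experiments measure.

Defaults mirror the running worked example: 5 criteria with latent
importances (5, 4, 3, 2, 1), 10 participants, 20 diseases, moderate
judgment noise sigma = 0.1.

All draws are deterministic given ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import ahp
from .config_io import (
    AnswerScale,
    AnswerTable,
    Criterion,
    PrioritizationConfig,
    Question,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Archetype",
    "SynthSpec",
    "gen_config",
    "gen_judgments",
    "gen_answers",
    "fixture_country_x",
    "rank_recovery_probability",
]


@dataclass(frozen=True)
class Archetype:
    """A disease profile: per-criterion category probabilities.

    ``probs`` maps criterion id to a probability vector over that
    question's categories (lowest category first); ``weight`` is the
    mixing proportion of the archetype in the disease list.
    """

    name: str
    weight: float
    probs: dict


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of a synthetic prioritization exercise."""

    n_criteria: int = 5
    n_participants: int = 10
    n_diseases: int = 20
    latent_weights: tuple[float, ...] | None = None
    judgment_noise: float = 0.1
    answer_model: tuple[Archetype, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        errors = []
        if self.n_criteria < 2:
            errors.append("n_criteria must be >= 2")
        if self.n_participants < 1:
            errors.append("n_participants must be >= 1")
        if self.n_diseases < 1:
            errors.append("n_diseases must be >= 1")
        if self.judgment_noise < 0:
            errors.append("judgment_noise (sigma) must be >= 0")
        lw = self.latent_weights
        if lw is None:
            lw = tuple(float(k) for k in range(self.n_criteria, 0, -1))
        else:
            lw = tuple(float(x) for x in lw)
            if len(lw) != self.n_criteria:
                errors.append(
                    f"latent_weights has {len(lw)} entries for "
                    f"{self.n_criteria} criteria"
                )
            if any(x <= 0 for x in lw):
                errors.append("latent_weights must be strictly positive")
        if self.answer_model is not None:
            am = tuple(self.answer_model)
            if any(a.weight < 0 for a in am) or sum(a.weight for a in am) <= 0:
                errors.append("archetype weights must be nonnegative, sum > 0")
            object.__setattr__(self, "answer_model", am)
        if errors:
            raise ValidationError(errors)
        object.__setattr__(self, "latent_weights", lw)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(f"c{i + 1}" for i in range(self.n_criteria))

    @property
    def latent_order(self) -> tuple[str, ...]:
        """Criterion ids sorted by descending latent importance."""
        v = np.asarray(self.latent_weights)
        order = sorted(range(self.n_criteria), key=lambda i: (-v[i], i))
        ids = self.criterion_ids
        return tuple(ids[i] for i in order)


def gen_config(spec: SynthSpec) -> PrioritizationConfig:
    """A synthetic configuration matching ``spec``.

    Questions alternate binomial (no/yes, 'yes' scoring 1) and 3-category
    ordinal (low/medium/high) scales.
    """
    criteria, questions = [], []
    for i, cid in enumerate(spec.criterion_ids):
        criteria.append(Criterion(id=cid, label=f"Criterion {i + 1}"))
        if i % 2 == 0:
            scale = AnswerScale(
                kind="binomial",
                categories=("no", "yes"),
                full_score_category="yes",
            )
        else:
            scale = AnswerScale(
                kind="multinomial", categories=("low", "medium", "high")
            )
        questions.append(
            Question(
                criterion_id=cid,
                text=f"Synthetic categorical question for criterion {i + 1}?",
                scale=scale,
                source_note="synthetic",
            )
        )
    diseases = tuple(
        f"disease_{i + 1:02d}" for i in range(spec.n_diseases)
    )
    return PrioritizationConfig(
        criteria=tuple(criteria),
        questions=tuple(questions),
        diseases=diseases,
        metadata={"purpose": "synthetic prioritization exercise"},
    )


def _noisy_matrices(
    rng: np.random.Generator,
    latent: np.ndarray,
    n_participants: int,
    sigma: float,
) -> list[np.ndarray]:
    n = latent.size
    base = np.outer(latent, 1.0 / latent)
    iu = np.triu_indices(n, 1)
    out = []
    clamped = 0
    for _ in range(n_participants):
        a = np.ones((n, n))
        vals = base[iu] * np.exp(rng.normal(0.0, sigma, size=iu[0].size))
        lo, hi = 1.0 / 9, 9.0
        clamped += int(np.sum((vals < lo) | (vals > hi)))
        vals = np.clip(vals, lo, hi)
        a[iu] = vals
        a[iu[1], iu[0]] = 1.0 / vals
        out.append(a)
    if clamped:
        total = n_participants * iu[0].size
        logger.info(
            "clamped %d/%d judgment values to the Saaty range [1/9, 9]",
            clamped,
            total,
        )
    return out


def gen_judgments(
    spec: SynthSpec, criteria_ids=None
) -> list[ahp.ParticipantJudgment]:
    """Simulate each participant's pairwise-comparison matrix.

    Deterministic given ``spec.seed``; participant ids are p01, p02, ...
    """
    ids = tuple(criteria_ids) if criteria_ids is not None else spec.criterion_ids
    if len(ids) != spec.n_criteria:
        raise ValidationError(
            f"{len(ids)} criteria ids for n_criteria={spec.n_criteria}"
        )
    rng = np.random.default_rng([spec.seed, 1])
    mats = _noisy_matrices(
        rng,
        np.asarray(spec.latent_weights),
        spec.n_participants,
        spec.judgment_noise,
    )
    return [
        ahp.ParticipantJudgment(
            participant_id=f"p{k + 1:02d}",
            matrix=ahp.PairwiseMatrix(ids, m),
        )
        for k, m in enumerate(mats)
    ]


def _default_archetypes(config: PrioritizationConfig) -> tuple[Archetype, ...]:
    probs = {}
    for cid in config.criterion_ids:
        m = len(config.question_for(cid).scale.categories)
        probs[cid] = [1.0 / m] * m
    return (Archetype(name="uniform", weight=1.0, probs=probs),)


def gen_answers(spec: SynthSpec, config: PrioritizationConfig) -> AnswerTable:
    """Draw a categorical answer table for every configured disease.

    Each disease is assigned an archetype (by the mixing weights) and its
    answer to each question is drawn from the archetype's per-criterion
    category probabilities.  Deterministic given ``spec.seed``.
    """
    archetypes = spec.answer_model or _default_archetypes(config)
    errors = []
    for a in archetypes:
        missing = [c for c in config.criterion_ids if c not in a.probs]
        if missing:
            errors.append(
                f"archetype {a.name!r}: missing probabilities for {missing}"
            )
            continue
        for cid in config.criterion_ids:
            cats = config.question_for(cid).scale.categories
            p = np.asarray(a.probs[cid], dtype=float)
            if p.size != len(cats):
                errors.append(
                    f"archetype {a.name!r}, criterion {cid!r}: "
                    f"{p.size} probabilities for {len(cats)} categories"
                )
            elif np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                errors.append(
                    f"archetype {a.name!r}, criterion {cid!r}: "
                    "probabilities must be nonnegative and sum to 1"
                )
    if errors:
        raise ValidationError(errors)
    rng = np.random.default_rng([spec.seed, 2])
    mix = np.asarray([a.weight for a in archetypes], dtype=float)
    mix = mix / mix.sum()
    rows = {}
    for disease in config.diseases:
        arch = archetypes[int(rng.choice(len(archetypes), p=mix))]
        row = {}
        for cid in config.criterion_ids:
            cats = config.question_for(cid).scale.categories
            p = np.asarray(arch.probs[cid], dtype=float)
            row[cid] = str(cats[int(rng.choice(len(cats), p=p / p.sum()))])
        rows[disease] = row
    return AnswerTable(rows=rows)


def rank_recovery_probability(
    spec: SynthSpec, n_replicates: int, seed: int | None = None
) -> float:
    """Fraction of replicate panels whose group ranking recovers the
    latent criterion order exactly.

    Each replicate simulates a fresh panel of ``spec.n_participants``
    judgments at ``spec.judgment_noise``, aggregates them (element-wise
    geometric mean, eigenvector priorities) and assigns sequential
    weights; recovery means the resulting ranking equals the descending
    latent order.  Deterministic given ``seed`` (default ``spec.seed``).
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    base_seed = spec.seed if seed is None else seed
    target = spec.latent_order
    hits = 0
    for rep in range(n_replicates):
        judgments = gen_judgments(
            replace(spec, seed=base_seed + 100_003 * rep)
        )
        group = ahp.aggregate_group(judgments, method="aij")
        ranking = ahp.assign_weights(group, spec.criterion_ids).ranking
        hits += ranking == target
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Country-X worked-example fixture

_COUNTRY_X_DISEASES = (
    "Rabies",
    "Anthrax",
    "Brucellosis",
    "Bovine tuberculosis",
    "Leptospirosis",
    "Q fever",
    "Rift Valley fever",
    "Highly pathogenic avian influenza",
    "Echinococcosis",
    "Cysticercosis",
    "Toxoplasmosis",
    "Trypanosomiasis",
    "Leishmaniasis",
    "Plague",
    "Tularemia",
    "Hantavirus infection",
    "Nipah virus infection",
    "Crimean-Congo haemorrhagic fever",
    "Lassa fever",
    "Bacterial Food-Borne Zoonoses",
)

#: Rabies' answers in the worked example: severity yes, bioterrorism no,
#: economic no, collaborate 'both', epidemic yes, giving weighted scores
#: 5 + 0 + 0 + 2 + 1 = 8 under weights severity=5 ... epidemic=1.
_RABIES_ANSWERS = {
    "severity": "yes",
    "bioterrorism": "no",
    "economic": "no",
    "collaborate": "both",
    "epidemic": "yes",
}


def fixture_country_x():
    """The packaged 'Country X' worked-example exercise.

    Returns ``(config, judgments, answers)``: a 5-criterion configuration
    (severity of illness, bioterrorism potential, economic burden,
    capacity to collaborate, epidemic potential), 10 participants whose
    perfectly consistent judgments share the latent importance vector
    (severity 5, bioterrorism 4, economic 3, collaborate 2, epidemic 1),
    and a 20-disease answer table.  Rabies carries the worked example's
    answer vector (total weighted score 8); the remaining 19 diseases'
    answers are synthetic, drawn once with a fixed seed.
    """
    criteria = (
        Criterion("bioterrorism", "Bioterrorism potential"),
        Criterion("severity", "Severity of illness in humans"),
        Criterion("economic", "Economic burden of disease"),
        Criterion("collaborate", "Capacity to collaborate"),
        Criterion("epidemic", "Epidemic potential"),
    )
    yn = AnswerScale(
        kind="binomial", categories=("no", "yes"), full_score_category="yes"
    )
    questions = (
        Question(
            "bioterrorism",
            "Is the pathogen listed as a select agent (Lists A, B, or C)?",
            yn,
            "CDC website",
        ),
        Question(
            "severity",
            "Is the case fatality rate for the pathogen in humans greater "
            "than 10%?",
            yn,
            "WHO website; country-specific literature",
        ),
        Question(
            "economic",
            "Does the pathogen cause more than 10% mortality in the animal "
            "population or more than a 10% decrease in animal productivity?",
            yn,
            "OIE website; country-specific literature",
        ),
        Question(
            "collaborate",
            "Do human or animal health laboratories have diagnostic "
            "capacity available for the pathogen in Country X?",
            AnswerScale(
                kind="multinomial",
                categories=("neither", "at least one", "both"),
            ),
            "Country X laboratory personnel",
        ),
        Question(
            "epidemic",
            "Has the pathogen been detected in a new location or population "
            "(human or animal) within Country X or any bordering country "
            "within the past 5 years?",
            yn,
            "Country X outbreak/surveillance data; ProMED; WHO; OIE",
        ),
    )
    config = PrioritizationConfig(
        criteria=criteria,
        questions=questions,
        diseases=_COUNTRY_X_DISEASES,
        metadata={
            "purpose": (
                "Determine which zoonoses will receive funding for joint "
                "surveillance projects between the human and animal health "
                "agencies of Country X"
            ),
            "jurisdiction": "Country X (fictitious worked example)",
        },
    )
    # latent importances aligned with the example ranking:
    # severity > bioterrorism > economic > collaborate > epidemic
    latent = {
        "severity": 5.0,
        "bioterrorism": 4.0,
        "economic": 3.0,
        "collaborate": 2.0,
        "epidemic": 1.0,
    }
    v = np.array([latent[c.id] for c in criteria])
    matrix = ahp.consistent_matrix(config.criterion_ids, v)
    judgments = [
        ahp.ParticipantJudgment(participant_id=f"p{k + 1:02d}", matrix=matrix)
        for k in range(10)
    ]
    rng = np.random.default_rng(2014)
    rows = {}
    for disease in config.diseases:
        if disease == "Rabies":
            rows[disease] = dict(_RABIES_ANSWERS)
            continue
        row = {}
        for cid in config.criterion_ids:
            cats = config.question_for(cid).scale.categories
            row[cid] = str(cats[int(rng.integers(len(cats)))])
        rows[disease] = row
    answers = AnswerTable(rows=rows)
    return config, judgments, answers
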