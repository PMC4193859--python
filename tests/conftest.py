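import numpy as np
import pytest

import zooprior as zp
from zooprior import config_io, synth
from zooprior.ahp import SAATY_SCALE


@pytest.fixture(scope="session")
def country_x():
    """The packaged worked-example exercise (config, judgments, answers)."""
    return synth.fixture_country_x()


@pytest.fixture(scope="session")
def country_x_weights(country_x):
    config, judgments, _ = country_x
    group = zp.aggregate_group(judgments)
    return zp.assign_weights(group, config.criterion_ids)


@pytest.fixture()
def country_x_files(tmp_path, country_x):
    """Worked-example inputs written out in the on-disk dialects."""
    config, judgments, answers = country_x
    config_io.save_config(config, tmp_path / "config.yaml")
    config_io.save_judgments(judgments, tmp_path / "judgments")
    config_io.answers_to_frame(answers, config).to_csv(
        tmp_path / "answers.csv", index=False
    )
    return tmp_path


from hypothesis import strategies as st


def _scale(kind, m):
    cats = tuple(f"cat{k}" for k in range(m))
    if kind == "binomial":
        return config_io.AnswerScale(
            "binomial", cats[:2], full_score_category=cats[1]
        )
    return config_io.AnswerScale("multinomial", cats)


@st.composite
def exercises(draw):
    """A small configuration, sequential weights, and a full answer table."""
    n_crit = draw(st.integers(2, 5))
    n_dis = draw(st.integers(1, 6))
    scales = [
        _scale(
            draw(st.sampled_from(["binomial", "multinomial"])),
            draw(st.integers(2, 4)),
        )
        for _ in range(n_crit)
    ]
    crits = tuple(
        config_io.Criterion(f"q{i}", f"Q{i}") for i in range(n_crit)
    )
    qs = tuple(
        config_io.Question(c.id, f"{c.id}?", s)
        for c, s in zip(crits, scales)
    )
    diseases = tuple(f"d{i}" for i in range(n_dis))
    config = config_io.PrioritizationConfig(crits, qs, diseases)
    perm = draw(st.permutations(list(config.criterion_ids)))
    n = len(perm)
    weights = zp.CriterionWeights(
        ranking=tuple(perm),
        priorities={
            c: (n - i) / (n * (n + 1) / 2) for i, c in enumerate(perm)
        },
        weights={c: float(n - i) for i, c in enumerate(perm)},
    )
    rows = {
        d: {
            q.criterion_id: draw(st.sampled_from(q.scale.categories))
            for q in qs
        }
        for d in diseases
    }
    return config, weights, config_io.AnswerTable(rows)


def raise_one_answer(config, answers, disease, cid):
    """Answers with one answer raised one ordinal category, or None if it
    is already at the top (binomial ordinal order: zero-score answer first)."""
    scale = config.question_for(cid).scale
    cur = answers.rows[disease][cid]
    if scale.kind == "binomial":
        order = (scale.lowest_category, scale.full_score_category)
    else:
        order = scale.categories
    k = order.index(cur)
    if k == len(order) - 1:
        return None
    rows = {d: dict(r) for d, r in answers.rows.items()}
    rows[disease][cid] = order[k + 1]
    return config_io.AnswerTable(rows)


def random_saaty_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random reciprocal matrix with upper-triangle entries drawn
    uniformly from the 17-value Saaty scale."""
    a = np.ones((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.choice(SAATY_SCALE, size=iu[0].size)
    a[iu] = vals
    a[iu[1], iu[0]] = 1.0 / vals
    return a
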