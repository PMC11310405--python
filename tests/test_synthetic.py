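import math

import numpy as np
import pytest

from mpnlp.ner import annotate_corpus
from mpnlp.synthetic import (CohortConfig, DocCountSpec, RenderConfig,
                             et_config, pv_config, render_corpus, sample_cohort)
from mpnlp.vocab import DM, EVENT_CONCEPTS, HTN, SMOKER


def test_prevalence_recovery_at_scale():
    """Empirical prevalence within 3 binomial SEs of configured for every concept."""
    cfg = et_config(10_000, seed=5)
    pheno = sample_cohort(cfg).phenotypes
    for concept, p in cfg.prevalence.items():
        se = math.sqrt(p * (1 - p) / cfg.n_patients)
        assert abs(pheno[concept].mean() - p) <= max(3 * se, 1e-12), concept


def test_htn_prevalence_near_cohort_rate():
    cfg = et_config(5600, seed=7)
    pheno = sample_cohort(cfg).phenotypes
    assert abs(pheno[HTN].mean() - 0.213) < 0.02


def test_conditional_link_matches_rejection_sampling_oracle():
    """P(HTN | DM) from the generator vs an independent two-stage sampler."""
    n = 10_000
    cfg = CohortConfig(
        cohort_name="ET", n_patients=n,
        prevalence={HTN: 0.213, DM: 0.046},
        conditional_links=((DM, HTN, 0.692),),
        te_rate=0.0, seed=13,
    )
    pheno = sample_cohort(cfg).phenotypes
    observed = pheno.loc[pheno[DM] == 1, HTN].mean()

    # oracle: explicit re-sampling with the closed-form complement rate
    rng = np.random.default_rng(99)
    p0 = (0.213 - 0.046 * 0.692) / (1 - 0.046)
    dm = rng.random(n) < 0.046
    htn = np.where(dm, rng.random(n) < 0.692, rng.random(n) < p0)
    expected = htn[dm].mean()

    n_dm = int(pheno[DM].sum())
    se = math.sqrt(0.692 * (1 - 0.692) / n_dm)
    assert abs(observed - expected) <= 3 * math.sqrt(2) * se
    assert abs(observed - 0.692) <= 3 * se
    # the marginal is preserved despite the link
    assert abs(pheno[HTN].mean() - 0.213) <= 3 * math.sqrt(0.213 * 0.787 / n)


def test_all_zero_prevalence_gives_empty_truth():
    cfg = CohortConfig(cohort_name="ET", n_patients=50,
                       prevalence={c: 0.0 for c in (HTN, DM, *EVENT_CONCEPTS)},
                       te_rate=0.2, seed=1)
    truth = sample_cohort(cfg)
    assert truth.phenotypes.to_numpy().sum() == 0
    assert truth.te_indicator().sum() == 0
    assert len(truth.event_strata) == 0


def test_inconsistent_link_rejected():
    cfg = CohortConfig(
        cohort_name="ET", n_patients=10,
        prevalence={HTN: 0.10, DM: 0.50},
        conditional_links=((DM, HTN, 0.692),),  # implies P(HTN|no DM) < 0
        seed=1,
    )
    with pytest.raises(ValueError, match="inconsistent link"):
        sample_cohort(cfg)


def test_event_prevalence_exceeding_te_rate_rejected():
    cfg = CohortConfig(cohort_name="ET", n_patients=10,
                       prevalence={EVENT_CONCEPTS[0]: 0.5},
                       te_rate=0.2, seed=1)
    with pytest.raises(ValueError, match="exceeds overall TE rate"):
        sample_cohort(cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(cohort_name="XX", n_patients=10, prevalence={})
    with pytest.raises(ValueError):
        CohortConfig(cohort_name="ET", n_patients=0, prevalence={})
    with pytest.raises(ValueError):
        CohortConfig(cohort_name="ET", n_patients=5, prevalence={HTN: 1.5})
    with pytest.raises(ValueError):
        CohortConfig(cohort_name="ET", n_patients=5, prevalence={HTN: 0.2},
                     te_odds_ratios={HTN: -1.0})
    with pytest.raises(ValueError):
        DocCountSpec(20, (34, 8))
    with pytest.raises(ValueError):
        RenderConfig(mean_mentions=-1)


def test_document_counts_match_cohort_median():
    truth = sample_cohort(et_config(560, seed=2))
    docs, _, _ = render_corpus(truth, RenderConfig(
        negated_rate=0, ambiguous_rate=0, other_subject_rate=0, seed=2))
    per_patient = {}
    for d in docs:
        per_patient[d.patient_id] = per_patient.get(d.patient_id, 0) + 1
    assert 15 <= np.median(list(per_patient.values())) <= 25


def test_mean_planted_mentions_matches_rate():
    """Sample-mean oracle: positive mentions per positive patient ~ rate 4."""
    n = 1000
    cfg = CohortConfig(cohort_name="ET", n_patients=n,
                       prevalence={HTN: 1.0}, te_rate=0.0, seed=3,
                       docs_per_patient=DocCountSpec(5, (3, 8)))
    truth = sample_cohort(cfg)
    _, gold, _ = render_corpus(truth, RenderConfig(
        mean_mentions=4.0, negated_rate=0, ambiguous_rate=0,
        other_subject_rate=0, seed=3))
    per_patient = {}
    for a in gold:
        pid = a.doc_id.split("-D")[0]
        per_patient[pid] = per_patient.get(pid, 0) + 1
    mean = sum(per_patient.values()) / n
    se = 2.0 / math.sqrt(n)  # Poisson(4) sd = 2
    assert abs(mean - 4.0) <= 3 * se


def test_zero_phenotypes_zero_noise_renders_no_vocabulary_terms(vocab):
    cfg = CohortConfig(cohort_name="ET", n_patients=20,
                       prevalence={c: 0.0 for c in (HTN, DM, SMOKER)},
                       te_rate=0.0, seed=4)
    truth = sample_cohort(cfg)
    docs, gold, _ = render_corpus(truth, RenderConfig(
        negated_rate=0, ambiguous_rate=0, other_subject_rate=0, seed=4))
    assert gold == []
    assert annotate_corpus(docs, vocab) == []


def test_rendering_is_seed_deterministic():
    truth = sample_cohort(et_config(30, seed=6))
    a = render_corpus(truth, RenderConfig(seed=6))
    b = render_corpus(truth, RenderConfig(seed=6))
    c = render_corpus(truth, RenderConfig(seed=7))
    assert a[0] == b[0] and a[1] == b[1]
    assert a[0] != c[0]


def test_pv_defaults_differ_from_et():
    et, pv = et_config(100, 1), pv_config(100, 1)
    assert pv.te_rate == 0.35 and et.te_rate == 0.20
    assert pv.docs_per_patient.median == 27
    assert pv.te_odds_ratios[HTN] == 1.5 and et.te_odds_ratios[HTN] == 2.5
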