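"""Synthetic-data generators: determinism, planted structure, closed-form checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mirsig.consensus import ConsensusParams, consensus_targets
from mirsig.io import write_gmt
from mirsig.network import RelationClass
from mirsig.synthetic import (
    ConfigurationError,
    SyntheticConfig,
    generate_annotation_db,
    generate_corpus,
    generate_interaction_db,
    generate_predictions,
    synthetic_lexicon,
)


def test_seeded_determinism_all_generators(small_config, tmp_path):
    out = []
    for _ in range(2):
        articles, truth = generate_corpus(small_config)
        preds = generate_predictions(small_config, truth)
        db = generate_annotation_db(small_config, truth)
        edges = generate_interaction_db(small_config, truth)
        gmt = tmp_path / f"r{len(out)}.gmt"
        write_gmt(db, gmt)
        out.append(
            (
                [(a.id, a.text, a.disease_flag) for a in articles],
                (preds.genes, preds.tools, preds.votes.tobytes()),
                gmt.read_bytes(),
                edges,
            )
        )
    assert out[0] == out[1]


def test_different_seed_changes_corpus(small_config):
    a1, _ = generate_corpus(small_config)
    a2, _ = generate_corpus(SyntheticConfig(**{**small_config.__dict__, "seed": 12}))
    assert [a.text for a in a1] != [a.text for a in a2]


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        SyntheticConfig(disease_rate=1.5)
    with pytest.raises(ConfigurationError):
        SyntheticConfig(gene_universe=())
    with pytest.raises(ConfigurationError):
        SyntheticConfig(planted_assoc={"NOT_IN_UNIVERSE": 2.0})
    with pytest.raises(ConfigurationError):
        SyntheticConfig(planted_assoc={"HG1": -1.0})
    with pytest.raises(ConfigurationError):
        SyntheticConfig(pathway_sizes=(10_000,))
    with pytest.raises(ConfigurationError):
        SyntheticConfig(tool_fpr=1.2)


def test_truth_sets_inside_universe(small_config):
    _, truth = generate_corpus(small_config)
    universe = set(small_config.gene_universe)
    assert truth.assoc_genes <= universe
    assert truth.target_genes <= universe
    for members in truth.pathway_membership.values():
        assert members <= universe


def test_comention_count_matches_closed_form_expectation():
    """Mean per-gene disease co-mention count over seeds matches
    n_articles * disease_rate * min(1, base_mention_rate * lift)."""
    lift = 8.0
    base = SyntheticConfig(
        n_articles=400,
        gene_universe=tuple(f"HG{i}" for i in range(1, 21)),
        planted_assoc={"HG1": lift},
        base_mention_rate=0.05,
        disease_rate=0.3,
        planted_targets=(),
        planted_pathway_membership={},
        pathway_sizes=(),
        planted_edges=(),
    )
    counts = []
    n_disease = []
    for seed in range(25):
        cfg = SyntheticConfig(**{**base.__dict__, "seed": seed})
        _, truth = generate_corpus(cfg)
        k = sum(
            1 for mentions, dz in zip(truth.article_mentions, truth.disease_flags)
            if dz and "HG1" in mentions
        )
        counts.append(k)
        n_disease.append(sum(truth.disease_flags))
    expected = 400 * 0.3 * min(1.0, 0.05 * lift)
    sd = math.sqrt(400 * 0.3 * 0.4 * 0.6 / 25) * 3  # ~3 sigma of the mean
    assert abs(np.mean(counts) - expected) < max(sd, 4.0)


def test_predictions_perfect_tools_recover_targets_exactly(small_config):
    cfg = SyntheticConfig(**{**small_config.__dict__, "tool_sensitivity": 1.0, "tool_fpr": 0.0})
    _, truth = generate_corpus(cfg)
    preds = generate_predictions(cfg, truth)
    assert set(preds.genes) == truth.target_genes
    assert preds.votes.all()


def test_predictions_zero_sensitivity_gives_targets_no_votes(small_config):
    cfg = SyntheticConfig(**{**small_config.__dict__, "tool_sensitivity": 0.0, "tool_fpr": 0.5})
    _, truth = generate_corpus(cfg)
    preds = generate_predictions(cfg, truth)
    assert not (set(preds.genes) & truth.target_genes)


def test_consensus_recovery_matches_binomial_tail():
    """Planted-target recovery at the vote threshold matches P(Bin(tools, sens) >= t)."""
    from scipy.stats import binom

    cfg = SyntheticConfig(
        n_articles=10,
        gene_universe=tuple(f"HG{i}" for i in range(1, 241)),
        planted_assoc={},
        planted_targets=tuple(f"HG{i}" for i in range(1, 201)),
        planted_pathway_membership={},
        pathway_sizes=(),
        planted_edges=(),
        tool_sensitivity=0.6,
        tool_fpr=0.05,
        n_tools=11,
    )
    hits = trials = 0
    for seed in range(15):
        c = SyntheticConfig(**{**cfg.__dict__, "seed": seed})
        _, truth = generate_corpus(c)
        preds = generate_predictions(c, truth)
        recovered = set(consensus_targets(preds, ConsensusParams(min_votes=4)))
        hits += len(recovered & truth.target_genes)
        trials += len(truth.target_genes)
    expected = float(binom.sf(3, 11, 0.6))
    rate = hits / trials
    mc_sd = math.sqrt(expected * (1 - expected) / trials)
    assert abs(rate - expected) < 4 * mc_sd + 1e-9


def test_annotation_db_honors_planted_membership(small_config):
    _, truth = generate_corpus(small_config)
    db = generate_annotation_db(small_config, truth)
    assert truth.pathway_membership["PW1"] <= db.sets["PW1"]
    assert len(db.sets["PW1"]) == small_config.pathway_sizes[0]
    # padding comes from the universe
    assert db.sets["PW1"] <= set(small_config.gene_universe)


def test_annotation_db_exact_when_size_equals_planted():
    cfg = SyntheticConfig(
        gene_universe=("A1", "A2", "A3", "A4"),
        planted_assoc={},
        planted_targets=(),
        planted_pathway_membership={"PW1": frozenset({"A1", "A2", "A3"})},
        pathway_sizes=(3,),
        planted_edges=(),
    )
    _, truth = generate_corpus(cfg)
    db = generate_annotation_db(cfg, truth)
    assert db.sets["PW1"] == {"A1", "A2", "A3"}


def test_interaction_db_zero_density_equals_planted(small_config):
    cfg = SyntheticConfig(**{**small_config.__dict__, "edge_density": 0.0})
    _, truth = generate_corpus(cfg)
    edges = generate_interaction_db(cfg, truth)
    got = {(e.pair[0], e.relation_class.value, e.pair[1]) for e in edges}
    want = {(min(s, t), c, max(s, t)) for s, c, t in truth.edge_list}
    assert got == want


def test_interaction_db_full_density_complete_graph():
    cfg = SyntheticConfig(
        gene_universe=("A1", "A2", "A3", "A4"),
        planted_assoc={},
        planted_targets=(),
        planted_pathway_membership={},
        pathway_sizes=(),
        planted_edges=(),
        edge_density=1.0,
    )
    _, truth = generate_corpus(cfg)
    edges = generate_interaction_db(cfg, truth)
    assert len({e.pair for e in edges}) == 6
    assert all(e.source != e.target for e in edges)


def test_interaction_db_density_within_binomial_error():
    n_pairs = math.comb(100, 2)
    counts = []
    for seed in range(10):
        cfg = SyntheticConfig(
            gene_universe=tuple(f"HG{i}" for i in range(1, 101)),
            planted_assoc={},
            planted_targets=(),
            planted_pathway_membership={},
            pathway_sizes=(),
            planted_edges=(),
            edge_density=0.1,
            seed=seed,
        )
        _, truth = generate_corpus(cfg)
        counts.append(len({e.pair for e in generate_interaction_db(cfg, truth)}))
    expected = 0.1 * n_pairs
    sd = math.sqrt(n_pairs * 0.1 * 0.9 / len(counts))
    assert abs(np.mean(counts) - expected) < 4 * sd


def test_substreams_independent(small_config):
    """Changing prediction parameters does not perturb the corpus stream."""
    a1, _ = generate_corpus(small_config)
    cfg2 = SyntheticConfig(**{**small_config.__dict__, "tool_fpr": 0.9})
    a2, _ = generate_corpus(cfg2)
    assert [a.text for a in a1] == [a.text for a in a2]


def test_lexicon_covers_universe(small_config):
    lex = synthetic_lexicon(small_config)
    assert set(lex.canonical_symbols) == set(small_config.gene_universe)
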