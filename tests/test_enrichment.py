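"""Hypergeometric term over-representation testing."""

from itertools import combinations

import numpy as np
import pytest

from tagdge import (AnnotationSet, SyntheticConfig, enrich,
                    generate_annotations, hypergeom_upper_tail,
                    make_paired_experiment)


class TestHypergeomUpperTail:
    def test_m_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_matches_exhaustive_enumeration(self):
        # N=10 genes, 5 in the term; draw 4; P[all 4 in term] = C(5,4)/C(10,4)
        p = hypergeom_upper_tail(4, 5, 4, 10)
        assert p == pytest.approx(5 / 210, abs=1e-12)
        # independent oracle: enumerate all C(10,4)=210 draws for every m
        term = set(range(5))
        draws = list(combinations(range(10), 4))
        for m in range(5):
            frac = sum(1 for d in draws if len(term & set(d)) >= m) / len(draws)
            assert hypergeom_upper_tail(m, 5, 4, 10) == pytest.approx(frac, abs=1e-12)

    @pytest.mark.parametrize("m,M,n,N", [(3, 20, 15, 100), (1, 5, 10, 50),
                                         (8, 40, 25, 200), (2, 10, 4, 30),
                                         (5, 12, 30, 60)])
    def test_matches_monte_carlo_draws(self, m, M, n, N):
        rng = np.random.default_rng(2024)
        reps = 1_000_000
        draws = rng.hypergeometric(M, N - M, n, size=reps)
        freq = float(np.mean(draws >= m))
        p = hypergeom_upper_tail(m, M, n, N)
        se = max(np.sqrt(p * (1 - p) / reps), 1e-6)
        assert abs(freq - p) <= 3 * se

    def test_monotone_decreasing_in_m(self):
        ps = [hypergeom_upper_tail(m, 30, 20, 100) for m in range(21)]
        assert all(ps[i + 1] <= ps[i] + 1e-15 for i in range(20))
        assert all(0 < p <= 1 for p in ps)

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 10, 100)  # m > M
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 200, 10, 100)  # M > N


def _annotations(mapping: dict[str, list[str]]) -> AnnotationSet:
    ann = AnnotationSet()
    for term, genes in mapping.items():
        for g in genes:
            ann.add(g, term)
    return ann


class TestEnrich:
    def test_degs_equal_background_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        ann = _annotations({"t1": genes[:4], "t2": genes[4:]})
        df = enrich(ann, set(genes), set(genes))
        assert (df["p_value"] == 1.0).all()

    def test_term_without_deg_members_has_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        ann = _annotations({"t1": genes[5:]})
        df = enrich(ann, set(genes[:3]), set(genes))
        assert df["p_value"].iloc[0] == 1.0

    def test_out_of_background_annotations_intersected(self):
        ann = _annotations({"t1": ["g1", "g2", "ghost1", "ghost2"]})
        background = {"g1", "g2", "g3", "g4"}
        df = enrich(ann, {"g1"}, background)
        assert df["M"].iloc[0] == 2  # ghosts removed before testing
        assert df["N"].iloc[0] == 4

    def test_stray_degs_dropped_with_warning(self, caplog):
        ann = _annotations({"t1": ["g1", "g2"]})
        with caplog.at_level("WARNING"):
            df = enrich(ann, {"g1", "not_in_bg"}, {"g1", "g2", "g3"})
        assert "dropped" in caplog.text
        assert df["n"].iloc[0] == 1

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError):
            enrich(AnnotationSet(), set(), set())

    def test_planted_term_ranks_first_in_most_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(n_genes=400, length_range=(100, 300),
                                  library_sizes=(1000, 1000), de_fraction=0.1,
                                  seed=seed)
            exp = make_paired_experiment(cfg)
            genes = list(exp.truth["gene_id"])
            ann = generate_annotations(genes, exp.truth, n_terms=30,
                                       planted_terms=1, seed=seed + 1000)
            degs = set(exp.truth.loc[exp.truth["is_de"], "gene_id"])
            df = enrich(ann, degs, set(genes))
            if df["term_id"].iloc[0].startswith("planted"):
                hits += 1
        assert hits >= 9

    def test_planted_term_beats_uniform_terms_in_expectation(self):
        # the planted term's p should be lower than the median uniform term's
        wins = 0
        for seed in range(6):
            cfg = SyntheticConfig(n_genes=300, length_range=(100, 300),
                                  library_sizes=(1000, 1000), de_fraction=0.1,
                                  seed=seed)
            exp = make_paired_experiment(cfg)
            genes = list(exp.truth["gene_id"])
            ann = generate_annotations(genes, exp.truth, n_terms=20,
                                       planted_terms=1, seed=seed)
            degs = set(exp.truth.loc[exp.truth["is_de"], "gene_id"])
            df = enrich(ann, degs, set(genes)).set_index("term_id")
            planted_p = df.loc[[t for t in df.index if t.startswith("planted")],
                               "p_value"].iloc[0]
            uniform_p = df.loc[[t for t in df.index if t.startswith("term")],
                               "p_value"].median()
            if planted_p < uniform_p:
                wins += 1
        assert wins == 6


class TestAnnotationIO:
    def test_tsv_round_trip(self, tmp_path):
        ann = _annotations({"t1": ["g1", "g2"], "t2": ["g3"]})
        path = tmp_path / "ann.tsv"
        ann.to_tsv(path)
        back = AnnotationSet.from_tsv(path)
        assert back.terms == ann.terms

    def test_generate_annotations_closure_and_empty(self, small_experiment):
        genes = list(small_experiment.truth["gene_id"])
        ann = generate_annotations(genes, small_experiment.truth, n_terms=15,
                                   planted_terms=2, seed=5)
        assert ann.annotated_genes <= set(genes)
        assert len(ann.terms) == 15
        empty = generate_annotations(genes, small_experiment.truth, n_terms=0,
                                     planted_terms=0, seed=5)
        assert empty.terms == {}

    def test_planted_exceeding_total_rejected(self, small_experiment):
        with pytest.raises(ValueError):
            generate_annotations(["g1"], small_experiment.truth, n_terms=1,
                                 planted_terms=2, seed=0)
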