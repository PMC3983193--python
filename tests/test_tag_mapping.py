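"""Tag-to-gene assignment, TPM quantification, saturation curves."""

import random

import numpy as np
import pytest

from tagdge import (CleanTagSet, ExpressionProfile, MapStatus, SyntheticConfig,
                    Transcript, build_clean_set, build_index,
                    make_paired_experiment, map_tag, one_mismatch_neighbors,
                    quantify, saturation_curve)
from tagdge.simulate import reads_to_strings
from tagdge.tag_library import TAG_LENGTH


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_assign(tag: str, index) -> tuple[str, str | None]:
    """Oracle: full Hamming scan of the index, exact hits taking priority."""
    exact = {t for t in index if t == tag}
    if exact:
        genes = index.genes(tag)
        return ("ambiguous", None) if len(genes) > 1 else ("exact", next(iter(genes)))
    genes: set[str] = set()
    for t in index:
        if hamming(t, tag) == 1:
            genes |= index.genes(t)
    if not genes:
        return ("unmapped", None)
    if len(genes) > 1:
        return ("ambiguous", None)
    return ("one_mismatch", next(iter(genes)))


def random_tag(rnd: random.Random) -> str:
    return "CATG" + "".join(rnd.choice("ACGT") for _ in range(17))


@pytest.fixture(scope="module")
def random_index():
    rnd = random.Random(99)
    transcripts = [Transcript(f"g{i:03d}", random_tag(rnd)) for i in range(500)]
    return build_index(transcripts)


class TestMapTag:
    def test_exact_unique_hit(self):
        idx = build_index([Transcript("g1", "CATG" + "A" * 17)])
        res = map_tag("CATG" + "A" * 17, idx)
        assert res.status is MapStatus.EXACT and res.gene_id == "g1"

    def test_distance_two_is_unmapped(self):
        idx = build_index([Transcript("g1", "CATG" + "A" * 17)])
        res = map_tag("CATG" + "CC" + "A" * 15, idx)
        assert res.status is MapStatus.UNMAPPED

    def test_one_mismatch_two_genes_ambiguous(self):
        idx = build_index([Transcript("g1", "CATG" + "A" * 17),
                           Transcript("g2", "CATG" + "C" + "A" * 16)])
        # query is 1 mismatch from both gene tags, exact hit of neither
        res = map_tag("CATG" + "G" + "A" * 16, idx)
        assert res.status is MapStatus.AMBIGUOUS

    def test_exact_hit_not_outvoted_by_neighbors(self):
        # the query exactly matches g1; g2 and g3 sit one mismatch away
        idx = build_index([Transcript("g1", "CATG" + "A" * 17),
                           Transcript("g2", "CATG" + "C" + "A" * 16),
                           Transcript("g3", "CATG" + "G" + "A" * 16)])
        res = map_tag("CATG" + "A" * 17, idx)
        assert res.status is MapStatus.EXACT and res.gene_id == "g1"

    def test_wrong_length_is_error(self, random_index):
        with pytest.raises(ValueError):
            map_tag("CATG", random_index)

    def test_agrees_with_brute_force_hamming_scan(self, random_index):
        rnd = random.Random(123)
        indexed = sorted(random_index)
        queries = []
        for _ in range(1000):
            mode = rnd.random()
            base = rnd.choice(indexed)
            if mode < 0.3:
                queries.append(base)  # exact
            elif mode < 0.7:  # one substitution away
                i = rnd.randrange(TAG_LENGTH)
                alt = rnd.choice([b for b in "ACGT" if b != base[i]])
                queries.append(base[:i] + alt + base[i + 1 :])
            else:
                queries.append(random_tag(rnd))
        for q in queries:
            res = map_tag(q, random_index)
            status, gene = brute_force_assign(q, random_index)
            assert (res.status.value, res.gene_id) == (status, gene), q


def test_neighbor_enumeration_is_63_distinct():
    tag = "CATG" + "A" * 17
    nbrs = one_mismatch_neighbors(tag)
    assert len(nbrs) == 63 == len(set(nbrs))
    assert all(hamming(n, tag) == 1 for n in nbrs)


class TestQuantify:
    def test_tpm_arithmetic(self):
        idx = build_index([Transcript("g1", "CATG" + "A" * 17),
                           Transcript("g2", "CATG" + "C" * 17)])
        clean = CleanTagSet(counts={"CATG" + "A" * 17: 5, "CATG" + "C" * 17: 15},
                            total_raw=20)
        profile, report = quantify(clean, idx)
        assert profile.tpm == {"g1": 250_000.0, "g2": 750_000.0}
        assert report.n_exact == 2

    def test_pure_noise_library_is_fully_unmapped(self):
        idx = build_index([Transcript("g1", "CATG" + "A" * 17)])
        clean = CleanTagSet(counts={"T" * 21: 4, "G" * 21: 3}, total_raw=7)
        profile, report = quantify(clean, idx)
        assert profile.counts == {}
        assert report.n_unmapped == report.n_distinct == 2

    def test_tpm_sum_identity_and_partition(self, small_profiles):
        for profile, report in [(small_profiles[0], small_profiles[2]),
                                (small_profiles[1], small_profiles[3])]:
            mapped = sum(profile.counts.values())
            assert sum(profile.tpm.values()) == pytest.approx(
                1e6 * mapped / profile.library_total, rel=1e-12)
            assert report.n_distinct == (report.n_exact + report.n_one_mismatch
                                         + report.n_ambiguous_discarded
                                         + report.n_unmapped)

    def test_counts_match_emitted_truth_under_sequencing_error(self):
        # with 1-mismatch rescue, >=99% of clean copies land on their source gene
        for seed in range(5):
            cfg = SyntheticConfig(n_genes=300, length_range=(100, 300),
                                  library_sizes=(100_000, 100_000),
                                  de_fraction=0.0, error_rate=0.005,
                                  singleton_noise_rate=0.0, seed=seed)
            exp = make_paired_experiment(cfg)
            idx = build_index(exp.transcripts)
            clean = build_clean_set(exp.reads_a)
            profile, _ = quantify(clean, idx)
            emitted = dict(zip(exp.truth["gene_id"], exp.truth["n_emitted_a"]))
            attributable = sum(min(profile.counts.get(g, 0), emitted[g])
                               for g in emitted)
            assert attributable / sum(profile.counts.values()) >= 0.99

    def test_empty_index_maps_nothing(self):
        clean = CleanTagSet(counts={"CATG" + "A" * 17: 3}, total_raw=3)
        profile, report = quantify(clean, build_index([]))
        assert profile.counts == {} and report.n_unmapped == 1


class TestSaturation:
    def test_grid_endpoints_and_monotonicity(self, small_experiment, small_index):
        reads = reads_to_strings(small_experiment.reads_a)
        n = len(reads)
        grid = [0, 100, 1000, 10_000, n]
        curve = saturation_curve(reads, small_index, grid, seed=4)
        depths, detected = zip(*curve)
        assert detected[0] == 0
        assert list(detected) == sorted(detected)  # non-decreasing
        # full depth equals whole-library detection
        full = {map_tag(t, small_index).gene_id for t in set(reads)
                if map_tag(t, small_index).gene_id is not None}
        assert detected[-1] == len(full)

    def test_depth_beyond_stream_is_error(self, small_index):
        with pytest.raises(ValueError):
            saturation_curve(["CATG" + "A" * 17] * 10, small_index, [11], seed=0)

    def test_monotone_for_any_seed(self, small_experiment, small_index):
        reads = reads_to_strings(small_experiment.reads_a[:3000])
        for seed in range(3):
            curve = saturation_curve(reads, small_index,
                                     [10, 50, 200, 1000, 3000], seed=seed)
            detected = [d for _, d in curve]
            assert detected == sorted(detected)


def test_profile_tsv_round_trip(tmp_path, small_profiles):
    profile = small_profiles[0]
    path = tmp_path / "profile.tsv"
    profile.to_tsv(path)
    back = ExpressionProfile.from_tsv(path)
    assert back.counts == profile.counts
    assert back.library_total == profile.library_total
    assert back.library_id == profile.library_id
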