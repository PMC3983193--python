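import pytest

from tagdge import (SyntheticConfig, build_clean_set, build_index,
                    make_paired_experiment, quantify)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_genes=200, length_range=(100, 400),
                           library_sizes=(30_000, 30_000), de_fraction=0.1,
                           de_log2fc_range=(2.0, 4.0), seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return make_paired_experiment(small_config)


@pytest.fixture(scope="session")
def small_index(small_experiment):
    return build_index(small_experiment.transcripts)


@pytest.fixture(scope="session")
def small_profiles(small_experiment, small_index):
    clean_a = build_clean_set(small_experiment.reads_a)
    clean_b = build_clean_set(small_experiment.reads_b)
    prof_a, rep_a = quantify(clean_a, small_index, library_id="A")
    prof_b, rep_b = quantify(clean_b, small_index, library_id="B")
    return prof_a, prof_b, rep_a, rep_b
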