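import numpy as np
import pytest

from synemg.synthetic import SubjectConfig, make_dataset


@pytest.fixture(scope="session")
def default_case():
    """Default synthetic subject + dataset (seeded, with noise)."""
    return make_dataset(seed=1)


@pytest.fixture(scope="session")
def noise_free_case():
    """Noise-free synthetic subject + dataset for closed-loop identities."""
    cfg = SubjectConfig(envelope_noise_sd=0.0, moment_noise_frac=0.0)
    return make_dataset(seed=1, config=cfg)


@pytest.fixture(scope="session")
def measured_activation_matrix(default_case):
    """(10, 10*100) activation matrix over the 10 evaluation cycles."""
    subject, dataset = default_case
    ds10 = dataset.subset(range(10))
    am = subject.model().activations(ds10.envelopes)
    return am.transpose(2, 0, 1).reshape(am.shape[2], -1)


def rank_stats_oracle(groups):
    """Brute-force Kruskal-Wallis H and Dunn z values from first principles.

    Independent of scipy and of synemg.evaluation: ranks are assigned by
    explicit sorting with tie averaging, H uses the textbook formula with
    the tie-correction divisor, and the Dunn z statistics use the
    tie-corrected rank variance.
    """
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    i = 0
    srt = pooled[order]
    while i < N:
        j = i
        while j + 1 < N and srt[j + 1] == srt[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1

    sizes = [len(g) for g in groups]
    edges = np.cumsum([0] + sizes)
    mean_ranks = [ranks[edges[k]:edges[k + 1]].mean() for k in range(len(groups))]

    H = 12.0 / (N * (N + 1)) * sum(
        n_i * rbar**2 for n_i, rbar in zip(sizes, mean_ranks)) - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    H /= 1.0 - tie_sum / (N**3 - N)

    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    z = {}
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z[(a, b)] = (mean_ranks[a] - mean_ranks[b]) / se
    return H, z
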