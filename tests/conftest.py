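import numpy as np
import pytest

from phyloseed import PatientConfig, VariantCallMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return PatientConfig(rng_seed=1)


def make_matrix(true_masks, n_samples, purity, rng, depth_range=(150, 400), vaf_scale=0.5, e=0.005, patient="synthetic"):
    """Synthetic count matrix: clonal variants at VAF purity*vaf_scale on their
    true sample pattern, read errors elsewhere."""
    m = len(true_masks)
    purity = np.asarray(purity, dtype=float)
    N = rng.integers(*depth_range, size=(m, n_samples))
    f = np.array(
        [[purity[s] * vaf_scale if (mask >> s) & 1 else 0.0 for s in range(n_samples)] for mask in true_masks]
    )
    theta = f * (1 - e) + (1 - f) * e / 3
    K = rng.binomial(N, theta)
    return VariantCallMatrix(
        patient_id=patient,
        samples=[f"S{i+1}" for i in range(n_samples)],
        variants=[f"v{i}" for i in range(m)],
        mut_reads=K,
        coverage=N,
        purity=purity,
    )


@pytest.fixture
def laminar_matrix(rng):
    """Noiseless-ish 4-sample matrix whose true patterns are laminar."""
    masks = [0b1111] * 5 + [0b0011] * 5 + [0b1100] * 5 + [0b0001] * 2 + [0b0100] * 2
    return make_matrix(masks, 4, np.full(4, 0.6), rng)


def random_laminar_masks(n, rng, max_parts=3):
    """Random laminar family over n samples (recursive partitioning)."""
    out = {(1 << n) - 1}

    def split(members):
        if len(members) < 2 or rng.random() < 0.3:
            return
        k = int(rng.integers(2, min(max_parts, len(members)) + 1))
        groups = [[] for _ in range(k)]
        order = list(members)
        rng.shuffle(order)
        for i, s in enumerate(order):
            groups[i % k].append(s)
        for g in groups:
            if 0 < len(g) < n:
                mask = 0
                for s in g:
                    mask |= 1 << s
                out.add(mask)
            split(g)

    split(list(range(n)))
    return sorted(out)
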