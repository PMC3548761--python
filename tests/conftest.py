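import numpy as np
import pytest

from epiccapo import classify, encoding, potentials_io, synthetic_data
from epiccapo.residues import AA_TO_INDEX, ALPHABETICAL


@pytest.fixture(scope="session")
def small_bundle():
    """A tiny deterministic system: 3 potentials, short HLA."""
    spec = synthetic_data.SyntheticSystemSpec(
        seed=42, n_aapps=3, hla_length=60, n_peptides=50
    )
    return synthetic_data.gen_system(spec)


@pytest.fixture(scope="session")
def small_encoder(small_bundle):
    return small_bundle.encoder()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_system(rng, n_aapps=2, hla_length=30):
    """A random valid (aapps, scaled psm, hla, cm) quadruple for oracle checks."""
    aapps = []
    for k in range(n_aapps):
        tri = rng.uniform(-3, 3, size=(20, 20))
        sym = np.tril(tri) + np.tril(tri, -1).T
        aapps.append(potentials_io.ContactPotentialMatrix(id=f"R{k}", values=sym))
    hla = potentials_io.HlaAllele(
        name="HLA-T*00:01",
        sequence="".join(rng.choice(list(ALPHABETICAL), size=hla_length)),
    )
    pairs = set()
    for i in range(1, 10):
        for j in rng.choice(hla_length, size=int(rng.integers(1, 5)), replace=False):
            pairs.add((i, int(j) + 1))
    cm = potentials_io.ContactMap(allele_name=hla.name, pairs=frozenset(pairs))
    raw = potentials_io.PositionalScoringMatrix(values=rng.normal(size=(9, 20)))
    return aapps, encoding.scale_psm(raw), hla, cm


def random_peptide(rng):
    return "".join(rng.choice(list(ALPHABETICAL), size=9))


def naive_capo_vector(peptide, aapps, psm, hla, cm):
    """Independent triple-loop evaluation of the encoding formula.

    Walks every (k, i, j) explicitly over the full HLA length using the 0/1
    contact indicator; stays independent of the lookup-table implementation.
    """
    seq = peptide.sequence if hasattr(peptide, "sequence") else peptide
    K = len(aapps)
    out = np.empty(9 * K)
    for k in range(K):
        for i in range(1, 10):
            u_i = seq[i - 1]
            num = 0.0
            den = 0
            for j in range(1, hla.length + 1):
                delta = 1 if (i, j) in cm.pairs else 0
                num += delta * aapps[k].values[AA_TO_INDEX[u_i], AA_TO_INDEX[hla.sequence[j - 1]]]
                den += delta
            out[9 * k + (i - 1)] = psm.values[i - 1, AA_TO_INDEX[u_i]] * num / den
    return out


def brute_force_auc(y, scores):
    """Pair-counting Mann-Whitney AUC: concordant pairs + half of ties."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_relieff(X, y, k_neighbors=10):
    """Independent O(n^2 F) Relief-F reference with plain Python loops."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, F = X.shape
    span = X.max(axis=0) - X.min(axis=0)

    def diff(f, r1, r2):
        if span[f] == 0:
            return 0.0
        return abs(X[r1, f] - X[r2, f]) / span[f]

    def dist(r1, r2):
        return sum(diff(f, r1, r2) for f in range(F))

    classes = sorted(set(y.tolist()))
    prior = {c: float(np.mean(y == c)) for c in classes}
    W = np.zeros(F)
    m = n
    for r in range(n):
        for c in classes:
            cand = [i for i in range(n) if y[i] == c and i != r]
            cand.sort(key=lambda i: (dist(r, i), i))
            neigh = cand[:k_neighbors]
            for nb in neigh:
                for f in range(F):
                    d = diff(f, r, nb)
                    if c == y[r]:
                        W[f] -= d / (m * k_neighbors)
                    else:
                        W[f] += prior[c] / (1 - prior[y[r]]) * d / (m * k_neighbors)
    return W
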