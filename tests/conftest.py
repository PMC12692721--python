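import numpy as np
import pytest

from featureforge.alphabets import full_alphabet, load_alphabets
from featureforge.protein_blocks import load_pb_set
from featureforge.synthetic import SyntheticChainSpec, gen_chain


@pytest.fixture(scope="session")
def pbset():
    return load_pb_set()


@pytest.fixture(scope="session")
def alphabet_catalog():
    return load_alphabets()


@pytest.fixture(scope="session")
def full5():
    return full_alphabet(5)


@pytest.fixture(scope="session")
def helix_chain():
    return gen_chain(SyntheticChainSpec(segments=(("helix", 20),), seed=1))


@pytest.fixture(scope="session")
def strand_chain():
    return gen_chain(SyntheticChainSpec(segments=(("strand", 20),), seed=2))


@pytest.fixture(scope="session")
def mixed_chains():
    """Small noisy corpus with helix/strand/coil segments for statistics."""
    chains = []
    for seed in range(6):
        spec = SyntheticChainSpec(
            segments=(("coil", 4), ("helix", 10), ("coil", 3),
                      ("strand", 8), ("coil", 5)),
            dihedral_noise_sd=8.0, seed=seed)
        chains.append(gen_chain(spec, chain_id=f"SYN{seed}"))
    return chains


def quaternion_rmsd(X, Y):
    """Independent superposition oracle (Horn's quaternion method)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Xc.T @ Yc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(Xc ** 2) + np.sum(Yc ** 2) - 2.0 * lam) / X.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


@pytest.fixture(scope="session")
def quaternion_oracle():
    return quaternion_rmsd
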