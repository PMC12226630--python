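import numpy as np
import pytest

from planefed.synthetic import EmbeddingClusterSpec, gen_embedding_clusters


@pytest.fixture(scope="session")
def gaussian_clusters():
    """Well-separated 4-class Gaussian clusters (separation = 6 sigma)."""
    spec = EmbeddingClusterSpec(
        n_classes=4, dim=32, n_per_class=100, separation=6.0, sigma=1.0, seed=0
    )
    X, y = gen_embedding_clusters(spec)
    return X, y, spec


class VectorEncoder:
    """Test stub satisfying the encoder contract: decodes a (1, d) 'image'
    holding an affinely squashed latent vector back to that vector.

    Images carry ``v / scale + offset`` (inside [0, 1] for the latent
    ranges used in tests); the 'embedding' is the recovered ``v``.
    """

    arch = "stub"

    def __init__(self, dim, scale=20.0, offset=0.5):
        self.embedding_dim = dim
        outer = self

        class _Net:
            @staticmethod
            def forward(x):
                return (x[:, 0, 0, :] - offset) * outer.scale

        self.scale = scale
        self.net = _Net()


@pytest.fixture
def vector_encoder():
    return VectorEncoder


def encode_vectors(X, scale=20.0, offset=0.5):
    """Turn latent vectors into the (1, d) pseudo-images VectorEncoder
    understands."""
    return [np.atleast_2d(v / scale + offset) for v in np.asarray(X)]
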