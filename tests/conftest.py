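import numpy as np
import pytest

from relayrt import IGParams, ModalityPair

# Benchmark unisensory IG fits used throughout: group-level audiovisual
# detection (miller1982), single-subject SOA study (miller1986).
MILLER1982 = ModalityPair(IGParams(399, 3272), IGParams(402, 7309))
MILLER1986 = ModalityPair(IGParams(231, 3931), IGParams(348, 4979))
OTTO_SOA = ModalityPair(IGParams(376, 8619), IGParams(404, 14225))

TABLE1_PARAMS = [
    IGParams(399, 3272),
    IGParams(402, 7309),
    IGParams(231, 3931),
    IGParams(348, 4979),
    IGParams(376, 8619),
    IGParams(404, 14225),
    IGParams(412, 13925),
    IGParams(457, 11711),
    IGParams(508, 7888),
    IGParams(431, 15486),
    IGParams(515, 9534),
]


@pytest.fixture
def miller1982():
    return MILLER1982


@pytest.fixture
def miller1986():
    return MILLER1986


@pytest.fixture
def otto_soa_pair():
    return OTTO_SOA


def ecdf_sup_distance(samples: np.ndarray, t: np.ndarray, cdf: np.ndarray) -> float:
    """Sup distance between an empirical CDF and a tabulated model CDF."""
    emp = np.searchsorted(np.sort(samples), t, side="right") / samples.size
    return float(np.max(np.abs(emp - cdf)))
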