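import random

import pytest
from hypothesis import HealthCheck, settings

from subfold import FoldOptions, eval_structure, fill_matrices, load_parameters

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEQ14 = "GCUCUAAAAGAGAG"


@pytest.fixture(scope="session")
def params():
    return load_parameters("default")


@pytest.fixture(scope="session")
def seq14():
    return SEQ14


def random_sequence(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


# ---------------------------------------------------------------------------
# independent structure predicates used as oracles


def has_lonely_pair(structure) -> bool:
    """A pair with no stacked neighbor on either side."""
    pairs = structure.pairs
    return any(
        (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs
        for i, j in pairs
    )


def max_branches_in_closed_pairs(structure) -> int:
    """Largest number of directly enclosed branches inside any closed pair."""
    pm = structure.partner_map()
    worst = 0
    for i, j in structure.pairs:
        k, branches = i + 1, 0
        while k < j:
            if k in pm and pm[k] > k:
                branches += 1
                k = pm[k] + 1
            else:
                k += 1
        worst = max(worst, branches)
    return worst


def brute_force_window_set(seq, brute, params, window, opts=None):
    """Energy-filtered oracle set: evaluate everything, keep <= mfe + w."""
    opts = opts or FoldOptions()
    m = fill_matrices(seq, params, options=opts)
    threshold = m.mfe_deci + round(window * 10)
    keep = set()
    for st in brute:
        deci = round(eval_structure(seq, st, params) * 10)
        if deci <= threshold:
            keep.add(st.to_dotbracket())
    return keep
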