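import numpy as np
import pytest

from amytrap.aggregation import AggregationParameters
from amytrap.sequence_matching import BURIED_ALLOWED, Template


@pytest.fixture
def agg_params():
    """Secondary-nucleation-dominated parameters at 2 uM monomer."""
    return AggregationParameters(kn=3e-4, kplus=3e6, k2=1e4, m_total=2e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_scan(template: Template, sequence: str) -> list[int]:
    """Independent per-window rule checker (oracle for scan_sequence).

    Deliberately written as a direct transcription of the matching rules,
    separate from the implementation: buried positions must hold one of
    F A M I L V S T Y G; proline is rejected at exposed positions except
    the first and last of the window.
    """
    n = template.length
    starts = []
    for s in range(len(sequence) - n + 1):
        ok = True
        for i in range(n):
            aa = sequence[s + i]
            if i in template.buried_idx:
                if aa not in "FAMILVSTYG":
                    ok = False
                    break
            else:
                if aa == "P" and i not in (0, n - 1):
                    ok = False
                    break
        if ok:
            starts.append(s)
    return starts


def regex_scan(template: Template, sequence: str) -> list[int]:
    """Regex oracle built character class by character class."""
    import re

    allowed = "".join(sorted(BURIED_ALLOWED))
    parts = []
    for i in range(template.length):
        if i in template.buried_idx:
            parts.append(f"[{allowed}]")
        elif i in (0, template.length - 1):
            parts.append("[A-Z]")
        else:
            parts.append("[A-OQ-Z]")  # any canonical letter range except P
    pattern = re.compile("(?=(" + "".join(parts) + "))")
    return [m.start() for m in pattern.finditer(sequence)]
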