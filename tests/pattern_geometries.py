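"""Interval geometries realizing each multistability arrangement.

Each entry maps a taxonomy class to stable stationary-state intervals and
a bursting range whose pairwise/higher-order overlaps reproduce exactly
that class's multiset of coexistence regime-sets.  Used to drive the
overlap machinery end to end (intervals -> coexistence -> scenario).
"""

import math

from hcoscan.continuation import StableInterval
from hcoscan.scan import BurstingRange


def _iv(label, lo, hi):
    v = -50.0 if label.startswith("hyp") else -20.0
    return StableInterval(label=label, g_min=lo, g_max=hi,
                          representative_v=v)


def pattern_geometry(cls: str, jitter: float = 0.0):
    """Return (intervals, bursting_range) realizing taxonomy class ``cls``.

    ``jitter`` shifts interval endpoints without changing the arrangement.
    """
    j = jitter
    if cls == "A":
        return ([_iv("hyp1", 3.0 + j, math.inf)],
                BurstingRange(g_min=1.0, g_max=4.0 + j))
    if cls == "B":
        return ([_iv("hyp1", 10.0 + j, math.inf), _iv("hyp2", 2.0, 3.0 + j)],
                BurstingRange(g_min=1.0, g_max=4.0))
    if cls == "C":
        return ([_iv("hyp1", 3.0, 4.5), _iv("dep1", 5.0, 6.0 + j),
                 _iv("dep2", 5.5, 7.0 + j)],
                BurstingRange(g_min=1.0, g_max=4.0))
    if cls == "D":
        return ([_iv("dep1", 0.0, 2.0 + j), _iv("hyp1", 5.0, math.inf)],
                BurstingRange(g_min=1.0, g_max=6.0 + j))
    if cls == "E":
        return ([_iv("dep1", 2.0, 5.0 + j), _iv("hyp1", 4.0 + j, math.inf)],
                BurstingRange(g_min=1.0, g_max=3.0))
    if cls == "F":
        return ([_iv("hyp1", 1.5, 2.5), _iv("dep1", 5.0, 8.0 + j),
                 _iv("dep2", 7.0, 9.0 + j)],
                BurstingRange(g_min=1.0, g_max=6.0))
    if cls == "G":
        return ([_iv("hyp1", 3.0, 6.0 + j), _iv("dep1", 2.0, 7.0 + j)],
                BurstingRange(g_min=1.0, g_max=4.0))
    if cls == "H":
        return ([_iv("dep1", 2.0, 3.5), _iv("hyp1", 3.0, 4.0 + j)],
                BurstingRange(g_min=1.0, g_max=6.0 + j))
    if cls == "I":
        return ([_iv("hyp1", 3.0, 6.0), _iv("dep1", 2.0, 8.0 + j),
                 _iv("dep2", 7.0, 9.0 + j)],
                BurstingRange(g_min=1.0, g_max=4.0))
    if cls == "J":
        return ([_iv("hyp1", 2.0, 8.0 + j), _iv("dep1", 3.0, 7.0 + j)],
                BurstingRange(g_min=4.0, g_max=6.0))
    raise ValueError(f"unknown class {cls!r}")
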