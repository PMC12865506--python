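"""Independent brute-force oracles used by the test suite.

Deliberately naive, loop-based re-statements of the extraction rules —
kept free of any code from the package modules they check.
"""

import math


def scan_peaks(days, p, rel_height=0.30):
    cut = rel_height * max(p)
    out = []
    for i in range(1, len(p) - 1):
        if p[i] > p[i - 1] and p[i] >= p[i + 1] and p[i] >= cut:
            out.append((int(days[i]), float(p[i])))
    return out


def _scan_minima(p):
    return [i for i in range(1, len(p) - 1) if p[i] < p[i - 1] and p[i] <= p[i + 1]]


def _cross(days, p, i_from, i_to, level, rising):
    for i in range(i_from + 1, i_to + 1):
        ok = p[i] >= level if rising else p[i] <= level
        if ok:
            prev_off = p[i - 1] < level if rising else p[i - 1] > level
            if prev_off and p[i] != p[i - 1]:
                frac = (level - p[i - 1]) / (p[i] - p[i - 1])
                return int(math.floor(days[i - 1] + frac * (days[i] - days[i - 1])))
            return int(math.floor(days[i]))
    return None


def scan_crossings(days, p, peaks, rel_height=0.30):
    minima = _scan_minima(p)
    cut = rel_height * max(p)
    last = len(p) - 1
    anchors = []
    for d, _ in peaks:
        anchors.append((list(days).index(d), True, True))
    if p[0] >= cut and len(p) > 1 and p[0] > p[1]:
        anchors.append((0, False, True))
    if p[last] >= cut and p[last] > p[last - 1]:
        anchors.append((last, True, False))
    anchors.sort()
    rises, declines = [], []
    for j, want_rise, want_decline in anchors:
        if want_rise and j > 0:
            pre = max([i for i in minima if i < j], default=0)
            if p[j] > p[pre]:
                d = _cross(days, p, pre, j, (p[pre] + p[j]) / 2.0, True)
                if d is not None:
                    rises.append(d)
        if want_decline and j < last:
            post = min([i for i in minima if i > j], default=last)
            if p[j] > p[post]:
                d = _cross(days, p, j, post, (p[post] + p[j]) / 2.0, False)
                if d is not None:
                    declines.append(d)
    return sorted(rises), sorted(declines)


def grid_threshold(b0, b1, target, step=0.001):
    """First score-grid point whose logistic precision reaches the target."""
    s = 0.0
    while s <= 1.0 + 1e-12:
        if 1.0 / (1.0 + math.exp(-(b0 + b1 * s))) >= target:
            return s
        s += step
    return None
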