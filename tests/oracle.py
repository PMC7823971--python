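"""Independent brute-force oracle for window profiling.

Deliberately naive: per-character tallies over string slices, no numpy,
no shared code with the implementation under test.
"""

from collections import Counter
from typing import Dict, List, Optional, Tuple

UPPER = "ACGT"
LOWER = "acgt"


def oracle_counts(residues: str, start: int, size: int) -> Tuple[Dict, Dict, int]:
    chunk = residues[start : start + size]
    tally = Counter(chunk)
    upper = {b: tally.get(b, 0) for b in UPPER}
    lower = {b: tally.get(b, 0) for b in LOWER}
    other = len(chunk) - sum(upper.values()) - sum(lower.values())
    return upper, lower, other


def oracle_metrics(upper: Dict, lower: Dict, other: int) -> Dict[str, Optional[float]]:
    upper_total = sum(upper.values())
    lower_total = sum(lower.values())
    counted = upper_total + lower_total
    gc_upper = upper["G"] + upper["C"]
    gc_lower = lower["g"] + lower["c"]

    def pct(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "gc_pct": pct(gc_upper + gc_lower, counted),
        "rep_pct": pct(lower_total, counted),
        "gc_pct_masked": pct(gc_lower, lower_total),
        "gc_pct_unmasked": pct(gc_upper, upper_total),
        "counted_bases": counted,
    }


def oracle_profile(residues: str, window_size: int) -> List[Dict]:
    """Window-by-window metrics of a sequence, brute force."""
    rows = []
    for k, start in enumerate(range(0, len(residues), window_size)):
        upper, lower, other = oracle_counts(residues, start, window_size)
        row = oracle_metrics(upper, lower, other)
        row["index"] = k + 1
        row["start_bp"] = start + 1
        row["upper"] = upper
        row["lower"] = lower
        row["other"] = other
        rows.append(row)
    return rows


def oracle_pearson(xs, ys) -> float:
    """Textbook two-pass Pearson correlation, pure Python."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / (sxx * syy) ** 0.5
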