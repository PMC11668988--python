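"""Independent brute-force references used to validate the fast paths.

These stay deliberately naive: feasibility is enumerated over all candidate
windows instead of scanned, so they share no code with the implementations
they check.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple


def brute_force_bouts(
    flags: Sequence[bool], min_span: int = 10, budget: int = 2
) -> List[Tuple[int, int]]:
    """All kept bouts as (start, end), by exhaustive window enumeration.

    A window [s, e] is feasible when both endpoints are active, its span is
    at least ``min_span``, and it contains at most ``budget`` inactive
    minutes.  Matching the documented greedy tie-break, the earliest
    feasible start is chosen and extended to its largest feasible end; the
    remainder of the sequence after the bout is processed recursively.
    """
    flags = list(bool(f) for f in flags)
    n = len(flags)
    prefix = [0]
    for f in flags:
        prefix.append(prefix[-1] + (1 if f else 0))

    def inactive_in(s: int, e: int) -> int:
        return (e - s + 1) - (prefix[e + 1] - prefix[s])

    bouts: List[Tuple[int, int]] = []
    offset = 0
    while offset < n:
        found = None
        for s in range(offset, n):
            if not flags[s]:
                continue
            best_e = None
            for e in range(s + min_span - 1, n):
                if flags[e] and inactive_in(s, e) <= budget:
                    best_e = e
            if best_e is not None:
                found = (s, best_e)
                break
        if found is None:
            break
        bouts.append(found)
        offset = found[1] + 1
    return bouts


def brute_force_inbout_active_minutes(
    flags: Sequence[bool], min_span: int = 10, budget: int = 2
) -> int:
    """Total active minutes covered by brute-force bouts."""
    flags = list(bool(f) for f in flags)
    total = 0
    for s, e in brute_force_bouts(flags, min_span, budget):
        total += sum(flags[s : e + 1])
    return total
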