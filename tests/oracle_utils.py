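"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's regex/scipy code paths: the term
oracle is a character-by-character scan and the interval oracle inverts
binomial tail probabilities by bisection on log-space summed pmfs.
"""

from __future__ import annotations

import math

_LETTERS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ")


def _chars_equal(a: str, b: str, case_sensitive: bool) -> bool:
    return a == b if case_sensitive else a.lower() == b.lower()


def _match_at(
    text: str,
    start: int,
    tokens: list[str],
    case_sensitive: bool,
    hyphen_space: bool,
) -> int | None:
    """Try to match the token sequence at ``start``; return the end offset."""
    sep_ok = (lambda c: c.isspace() or c == "-") if hyphen_space else str.isspace
    i = start
    for t_idx, token in enumerate(tokens):
        if t_idx > 0:
            j = i
            while j < len(text) and sep_ok(text[j]):
                j += 1
            if j == i:
                return None
            i = j
        for ch in token:
            if i >= len(text) or not _chars_equal(text[i], ch, case_sensitive):
                return None
            i += 1
    return i


def naive_occurrences(
    text: str,
    term: str,
    case_sensitive: bool = False,
    whole_word: bool = True,
    hyphen_space: bool = True,
) -> list[tuple[int, int]]:
    """All occurrences of one term by scanning every start position."""
    tokens = term.split()
    occs = []
    for start in range(len(text)):
        end = _match_at(text, start, tokens, case_sensitive, hyphen_space)
        if end is None:
            continue
        if whole_word:
            if start > 0 and text[start - 1] in _LETTERS:
                continue
            if end < len(text) and text[end] in _LETTERS:
                continue
        occs.append((start, end))
    return occs


def naive_matches(
    sentence: str,
    terms: tuple[str, ...],
    case_sensitive: bool = False,
    whole_word: bool = True,
    hyphen_space: bool = True,
) -> list[tuple[str, int, int]]:
    """All-term occurrence scan with containment collapsing: drop any
    occurrence strictly contained in a longer one."""
    all_occs = [
        (s, e, term)
        for term in terms
        for (s, e) in naive_occurrences(
            sentence, term, case_sensitive, whole_word, hyphen_space
        )
    ]
    kept = []
    for s, e, term in all_occs:
        contained = any(
            s2 <= s and e <= e2 and (e2 - s2) > (e - s) for s2, e2, _ in all_occs
        )
        if not contained:
            kept.append((term, s, e))
    kept.sort(key=lambda t: (t[1], t[2]))
    return kept


# --- exact binomial interval by bisection ---------------------------------


def _binom_tail_geq(n: int, x: int, p: float, log_comb: list[float]) -> float:
    """P(X >= x) for X ~ Binomial(n, p), summed in log space."""
    if x <= 0:
        return 1.0
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    lp, lq = math.log(p), math.log1p(-p)
    return math.fsum(
        math.exp(log_comb[k] + k * lp + (n - k) * lq) for k in range(x, n + 1)
    )


def bisect_clopper_pearson(
    x: int, n: int, level: float = 0.95, iters: int = 80
) -> tuple[float, float]:
    """Invert the binomial tails by bisection.

    lower solves P(X >= x | p) = alpha/2 (increasing in p);
    upper solves P(X <= x | p) = alpha/2 (decreasing in p).
    """
    alpha = 1.0 - level
    log_comb = [
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        for k in range(n + 1)
    ]
    if x == 0:
        lower = 0.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(iters):
            mid = (lo + hi) / 2.0
            if _binom_tail_geq(n, x, mid, log_comb) < alpha / 2.0:
                lo = mid
            else:
                hi = mid
        lower = (lo + hi) / 2.0
    if x == n:
        upper = 1.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(iters):
            mid = (lo + hi) / 2.0
            if 1.0 - _binom_tail_geq(n, x + 1, mid, log_comb) > alpha / 2.0:
                lo = mid
            else:
                hi = mid
        upper = (lo + hi) / 2.0
    return lower, upper
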