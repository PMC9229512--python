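"""Independent brute-force oracles shared by the test modules."""


def binomial_pmf(n: int, p: float) -> list[float]:
    """Exact-recurrence binomial pmf, floats (stable for the tail sums used here)."""
    pmf = [(1.0 - p) ** n]
    ratio = p / (1.0 - p)
    for k in range(n):
        pmf.append(pmf[-1] * (n - k) / (k + 1) * ratio)
    return pmf


def oracle_tolerance_ranks(n: int, coverage: float = 0.95, confidence: float = 0.95):
    """Order-statistic ranks bracketing the population (1-coverage) quantile,
    found by direct summation of binomial tail probabilities."""
    pmf = binomial_pmf(n, 1.0 - coverage)
    outer = None
    upper_tail = 1.0 - pmf[0]  # Pr[Bin >= 1]
    r = 1
    while upper_tail >= confidence:
        outer = r
        upper_tail -= pmf[r]
        r += 1
    if outer is None:
        return None
    inner = outer
    cdf = sum(pmf[:inner])  # Pr[Bin < inner]
    while cdf < confidence:
        cdf += pmf[inner]
        inner += 1
    return outer, inner
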