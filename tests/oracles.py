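"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own scanning/statistics code paths:
site strings come from Biopython's reverse complement, matching is plain
window enumeration, and ANOVA is textbook sums of squares.
"""

from __future__ import annotations

from Bio.Seq import Seq

CLASS_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer", "6mer-offset")


def oracle_site_strings(guide: str) -> dict[str, str]:
    g = guide.upper().replace("T", "U")
    rc = lambda s: str(Seq(s).reverse_complement_rna())
    return {
        "8mer": rc(g[1:8]) + "A",
        "7mer-m8": rc(g[1:8]),
        "7mer-A1": rc(g[1:7]) + "A",
        "6mer": rc(g[1:7]),
        "6mer-offset": rc(g[2:8]),
    }


def oracle_matches(guide: str, target: str, mode: str) -> list[tuple[str, int]]:
    """Slide every window of widths 6-8 and string-compare against the sites."""
    seq = target.upper().replace("T", "U")
    sites = oracle_site_strings(guide)
    all_matches = []  # (class, start, end)
    for cls in CLASS_ORDER:
        site = sites[cls]
        w = len(site)
        for start in range(len(seq) - w + 1):
            if seq[start:start + w] == site:
                all_matches.append((cls, start, start + w))
    if mode == "overlapping":
        return [(c, s) for c, s, _ in all_matches]
    # hierarchical: visit classes longest-first (CLASS_ORDER is so ordered);
    # a match contained in an already-kept footprint is suppressed
    kept, footprints = [], []
    for cls in CLASS_ORDER:
        for c, s, e in all_matches:
            if c != cls:
                continue
            if any(a <= s and e <= b for a, b in footprints):
                continue
            kept.append((c, s))
            footprints.append((s, e))
    return kept


def oracle_anova(groups: list[list[float]]) -> tuple[float, int, int]:
    """One-way ANOVA F and degrees of freedom by explicit sums of squares."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, k - 1, n - k
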