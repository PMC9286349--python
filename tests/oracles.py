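"""Independent brute-force reference implementations used only by tests.

Everything here is written to be obviously correct and slow: nested loops and
naive scans, no indexes, no short-circuits.  The package must agree with these
on small instances.
"""

from __future__ import annotations

from math import comb


def naive_occurrences(entries, query):
    """All (accession, start, end) occurrences by scanning every position."""
    out = []
    for acc, seq in entries:
        for i in range(len(seq) - len(query) + 1):
            if seq[i : i + len(query)] == query:
                out.append((acc, i, i + len(query)))
    return out


def brute_force_explanations(peptide, entries, max_intervening=25, min_reactant_len=1):
    """Complete explanation set as a set of plain tuples.

    Tuple forms:
      ("NONSPLICED", occ)
      ("CIS_NORMAL"|"CIS_REVERSE", left_occ, right_occ, split_point, intervening)
      ("TRANS", left_occ, right_occ, split_point)
    Overlapping same-protein reactant pairs are not explanations, and
    same-protein pairs outside the intervening window explain nothing
    (mirroring the mapper defaults).
    """
    out = set()
    for occ in naive_occurrences(entries, peptide):
        out.add(("NONSPLICED", occ))
    n = len(peptide)
    for s in range(min_reactant_len, n - min_reactant_len + 1):
        left, right = peptide[:s], peptide[s:]
        for lo in naive_occurrences(entries, left):
            for ro in naive_occurrences(entries, right):
                if lo[0] != ro[0]:
                    out.add(("TRANS", lo, ro, s))
                    continue
                gap_normal = ro[1] - lo[2]
                gap_reverse = lo[1] - ro[2]
                if 0 <= gap_normal <= max_intervening:
                    out.add(("CIS_NORMAL", lo, ro, s, gap_normal))
                elif 0 <= gap_reverse <= max_intervening:
                    out.add(("CIS_REVERSE", lo, ro, s, gap_reverse))
    return out


def brute_force_category(peptide, entries, max_intervening=25):
    expls = brute_force_explanations(peptide, entries, max_intervening)
    kinds = {e[0] for e in expls}
    if "NONSPLICED" in kinds:
        return "NONSPLICED"
    if "CIS_NORMAL" in kinds or "CIS_REVERSE" in kinds:
        return "CIS"
    if "TRANS" in kinds:
        return "TRANS"
    return "NONE"


def explanation_to_tuple(expl):
    """Convert a SpliceExplanation into the oracle's tuple form."""
    lo = expl.left_reactant.as_tuple()
    if expl.category == "NONSPLICED":
        return ("NONSPLICED", lo)
    ro = expl.right_reactant.as_tuple()
    if expl.category == "TRANS":
        return ("TRANS", lo, ro, expl.split_point)
    return (expl.category, lo, ro, expl.split_point, expl.intervening_len)


def hypergeom_tail(m, n_bins, n_peaks, n_frag):
    """P(X >= m) for X ~ Hypergeometric(n_bins, n_peaks, n_frag) by direct sum."""
    total = 0.0
    for k in range(m, min(n_peaks, n_frag) + 1):
        total += comb(n_peaks, k) * comb(n_bins - n_peaks, n_frag - k) / comb(n_bins, n_frag)
    return total
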