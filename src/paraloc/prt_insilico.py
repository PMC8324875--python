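"""In-silico evaluation of paralogue-ratio-test (PRT) primer pairs.

A PRT uses a single primer pair that amplifies several paralogues into
products of distinguishable sizes.  This module checks a primer pair
against a set of templates with IUPAC-degenerate-aware matching: a
template amplifies when both primers find sites with fewer than five
mismatches (the specificity rule used when designing such assays —
non-amplified paralogues must carry at least five mismatches), and the
predicted product runs from the forward primer's 5' start to the reverse
primer's 5' start inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PrimerPair",
    "PredictedAmplicon",
    "IUPAC",
    "iupac_match",
    "count_mismatches",
    "predict_amplicons",
    "specificity_report",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "K": frozenset("GT"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "R": frozenset("AG"), "W": frozenset("AT"), "S": frozenset("CG"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "K": "M", "M": "K", "Y": "R", "R": "Y", "W": "W", "S": "S",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def iupac_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    label: str = ""

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes {sorted(bad)}")


@dataclass
class PredictedAmplicon:
    template_id: str
    product_length: int | None
    forward_mismatches: int | None
    reverse_mismatches: int | None
    amplified: bool
    forward_start: int | None = None  # 5' start on the template plus strand
    reverse_start: int | None = None


def iupac_match(primer_char: str, template_char: str) -> bool:
    """True iff the template base is in the primer code's expansion."""
    return template_char.upper() in IUPAC[primer_char.upper()]


def count_mismatches(primer: str, template_window: str,
                     orientation: str = "forward") -> int:
    """Mismatches between a primer and a template window of equal length.

    ``orientation='reverse'`` counts the reverse primer against a
    plus-strand window: the primer anneals to the minus strand, so the
    window is compared against the primer's reverse complement.
    """
    if len(primer) != len(template_window):
        raise ValueError("window length must equal primer length")
    if orientation == "reverse":
        primer = iupac_revcomp(primer)
    return sum(
        0 if iupac_match(p, t) else 1
        for p, t in zip(primer.upper(), template_window.upper())
    )


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _scan(primer: str, template: str, orientation: str) -> np.ndarray:
    """Mismatch count at every window start (vectorised over offsets)."""
    if orientation == "reverse":
        primer = iupac_revcomp(primer)
    k, n = len(primer), len(template)
    if n < k:
        return np.zeros(0, dtype=int)
    t = np.array([_BASE_IDX.get(c, 4) for c in template.upper()], dtype=np.int8)
    mism = np.zeros(n - k + 1, dtype=int)
    for j, p in enumerate(primer.upper()):
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC[p]:
            allowed[_BASE_IDX[b]] = True
        mism += ~allowed[t[j:j + n - k + 1]]
    return mism


def _terminal_mismatch(primer: str, template: str, orientation: str) -> np.ndarray:
    """Per-offset flag: does the primer's 3'-terminal base mismatch?

    On the plus strand the forward primer's 3' end is the last window
    position; the reverse primer (annealing to the minus strand) has its
    3' end at the first window position.
    """
    if orientation == "reverse":
        rc = iupac_revcomp(primer)
        term_off, term_char = 0, rc[0]
    else:
        term_off, term_char = len(primer) - 1, primer[-1]
    k, n = len(primer), len(template)
    if n < k:
        return np.zeros(0, dtype=bool)
    allowed = IUPAC[term_char]
    return np.array([template[i + term_off].upper() not in allowed
                     for i in range(n - k + 1)])


def predict_amplicons(
    pair: PrimerPair,
    templates: dict[str, str],
    max_product: int = 3000,
    amplify_below: int = 5,
    search_both_strands: bool = True,
    three_prime_veto: bool = False,
) -> list[PredictedAmplicon]:
    """Best predicted product per template.

    Scans each template (and, by default, its reverse complement) for
    forward-primer sites and downstream reverse-primer sites within
    ``max_product``; a template amplifies when its best site pair has
    fewer than ``amplify_below`` mismatches on both primers.  Product
    length = reverse 5' start − forward 5' start + 1.  Templates with no
    qualifying site pair report their least-bad pair with
    ``amplified=False``.
    """
    out = []
    for tid, template in templates.items():
        strands = [template]
        if search_both_strands:
            strands.append(iupac_revcomp(template))
        best = None  # (worst_mm, total_mm, fmm, rmm, length, fstart, rstart)
        for seq in strands:
            fm = _scan(pair.forward, seq, "forward")
            rm = _scan(pair.reverse, seq, "reverse")
            if len(fm) == 0 or len(rm) == 0:
                continue
            if three_prime_veto:
                # a mismatched 3'-terminal base blocks extension entirely
                fm = fm + amplify_below * _terminal_mismatch(
                    pair.forward, seq, "forward")
                rm = rm + amplify_below * _terminal_mismatch(
                    pair.reverse, seq, "reverse")
            lf, lr = len(pair.forward), len(pair.reverse)
            # consider forward sites in increasing mismatch order; for each,
            # the best reverse site downstream within max_product
            for i in np.argsort(fm, kind="stable"):
                jlo = i  # reverse site must start at/after the forward site
                jhi = min(len(rm) - 1, i + max_product - lr)
                if jhi < jlo:
                    continue
                window = rm[jlo:jhi + 1]
                j_rel = int(np.argmin(window))
                j = jlo + j_rel
                length = j + lr - i
                cand = (max(int(fm[i]), int(window[j_rel])),
                        int(fm[i]) + int(window[j_rel]),
                        int(fm[i]), int(window[j_rel]), length, int(i), j + lr - 1)
                if best is None or cand[:2] < best[:2]:
                    best = cand
                if fm[i] == 0 and window[j_rel] == 0:
                    break
        if best is None:
            out.append(PredictedAmplicon(tid, None, None, None, False))
            continue
        _, _, fmm, rmm, length, fstart, rstart = best
        amplified = fmm < amplify_below and rmm < amplify_below
        out.append(PredictedAmplicon(
            tid, length if amplified else length, fmm, rmm, amplified,
            fstart, rstart,
        ))
    return out


def specificity_report(
    pair: PrimerPair,
    templates: dict[str, str],
    max_product: int = 3000,
    amplify_below: int = 5,
    gel_resolution: int = 20,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-template amplification table plus collision warnings.

    Warns when two amplified products differ by less than the gel
    resolution margin (they would not be separable by size), and flags an
    assay that amplifies nothing as uninformative.
    """
    preds = predict_amplicons(pair, templates, max_product, amplify_below)
    rows = [
        {
            "assay": pair.label,
            "template": p.template_id,
            "amplified": p.amplified,
            "product_length": p.product_length if p.amplified else None,
            "forward_mismatches": p.forward_mismatches,
            "reverse_mismatches": p.reverse_mismatches,
        }
        for p in preds
    ]
    warnings = []
    amplified = [(p.template_id, p.product_length) for p in preds if p.amplified]
    for i in range(len(amplified)):
        for j in range(i + 1, len(amplified)):
            (ta, la), (tb, lb) = amplified[i], amplified[j]
            if abs(la - lb) < gel_resolution:
                warnings.append(
                    f"products for {ta} ({la} bp) and {tb} ({lb} bp) differ "
                    f"by {abs(la - lb)} bp (< {gel_resolution} bp resolution)"
                )
    if not amplified:
        warnings.append("assay uninformative: no template amplifies")
    return pd.DataFrame(rows), warnings
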