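"""Genotype calling from fragment sizes.

Two assays: an ApoI restriction digest for rs7341475 (the A allele carries an
extra cut site, so A digests to 233+158+30 bp while G gives 233+188 bp), and
a fluorescent PCR across the promoter GGC repeat whose fragment length is a
fixed base size plus 3 bp per repeat.  Sizes arrive from gel or capillary
sizing and carry jitter, so matching uses tolerances: +/-2 bp for RFLP
fragments, +/-1 bp residue for the repeat arithmetic.  The 30 bp ApoI
fragment routinely runs off a 3% agarose gel, so an A-pattern missing only
the 30 bp band is still accepted (with a QC note).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GenotypeCall",
    "call_rflp",
    "call_ggc",
    "call_rflp_table",
    "call_ggc_table",
    "COMMON_REPEATS",
]

RFLP_TOL = 2.0
GGC_RESIDUE_TOL = 1.0
#: The two common GGC alleles; everything longer is rare.
COMMON_REPEATS = frozenset({8, 10})

_G_FRAG = (233.0, 188.0)
_A_FRAG = (233.0, 158.0, 30.0)


@dataclass
class GenotypeCall:
    sample_id: str
    marker: str
    call: str | None  # 'AA'/'AG'/'GG' or 'r1/r2'; None = no-call
    qc: str = "PASS"


def _match(size: float, expected: float, tol: float) -> bool:
    return abs(size - expected) <= tol


def call_rflp(sizes, sample_id: str = "", tol: float = RFLP_TOL) -> GenotypeCall:
    """ApoI fragment sizes -> rs7341475 genotype.

    {233,158,30} -> AA; {233,188} -> GG; union of both -> AG; {233,158}
    -> AA with a note (30 bp below gel detection).  Any unmatched or missing
    fragment produces a no-call.
    """
    marker = "rs7341475"
    sizes = sorted((float(s) for s in sizes), reverse=True)
    if not sizes:
        return GenotypeCall(sample_id, marker, None, "empty_profile")
    expected = {233.0, 188.0, 158.0, 30.0}
    present: set[float] = set()
    for s in sizes:
        hits = [e for e in expected if _match(s, e, tol)]
        if not hits:
            return GenotypeCall(sample_id, marker, None, f"unexpected_fragment_{s:g}bp")
        present.add(min(hits, key=lambda e: abs(e - s)))
    if 233.0 not in present:
        return GenotypeCall(sample_id, marker, None, "missing_233bp")
    has_g = 188.0 in present
    has_a = 158.0 in present
    if has_a and has_g:
        return GenotypeCall(sample_id, marker, "AG")
    if has_g and not has_a:
        if 30.0 in present:
            return GenotypeCall(sample_id, marker, None, "orphan_30bp")
        return GenotypeCall(sample_id, marker, "GG")
    if has_a and not has_g:
        qc = "PASS" if 30.0 in present else "30bp_not_detected"
        return GenotypeCall(sample_id, marker, "AA", qc)
    return GenotypeCall(sample_id, marker, None, "uninterpretable")


def call_ggc(
    sizes,
    base_size: float,
    sample_id: str = "",
    residue_tol: float = GGC_RESIDUE_TOL,
) -> GenotypeCall:
    """Fragment length(s) -> GGC repeat-count pair.

    repeat = round((size - base_size)/3); one observed size collapses to a
    homozygous pair.  A residue beyond the tolerance, or a profile with more
    than two sizes, is a no-call.  Calls containing an allele outside the two
    common lengths (8, 10) are flagged 'rare_allele'.
    """
    marker = "ggc_repeat"
    sizes = sorted(float(s) for s in sizes)
    if not sizes or len(sizes) > 2:
        return GenotypeCall(sample_id, marker, None, "bad_profile")
    reps = []
    for s in sizes:
        r = round((s - base_size) / 3.0)
        if r < 1 or abs((s - base_size) - 3.0 * r) > residue_tol:
            return GenotypeCall(sample_id, marker, None, f"off_ladder_{s:g}bp")
        reps.append(int(r))
    if len(reps) == 1:
        reps = [reps[0], reps[0]]
    reps.sort()
    qc = "PASS" if all(r in COMMON_REPEATS for r in reps) else "rare_allele"
    return GenotypeCall(sample_id, marker, f"{reps[0]}/{reps[1]}", qc)


def _parse_sizes(field: str) -> list[float]:
    return [float(tok) for tok in str(field).split(";") if tok]


def call_rflp_table(fragments: pd.DataFrame, tol: float = RFLP_TOL) -> pd.DataFrame:
    calls = [
        call_rflp(_parse_sizes(row["fragment_sizes"]), row["sample_id"], tol)
        for _, row in fragments.iterrows()
    ]
    return pd.DataFrame(
        {"sample_id": [c.sample_id for c in calls], "marker": "rs7341475",
         "call": [c.call for c in calls], "qc": [c.qc for c in calls]}
    )


def call_ggc_table(
    fragments: pd.DataFrame, base_size: float, residue_tol: float = GGC_RESIDUE_TOL
) -> pd.DataFrame:
    calls = [
        call_ggc(_parse_sizes(row["fragment_sizes"]), base_size, row["sample_id"], residue_tol)
        for _, row in fragments.iterrows()
    ]
    return pd.DataFrame(
        {"sample_id": [c.sample_id for c in calls], "marker": "ggc_repeat",
         "call": [c.call for c in calls], "qc": [c.qc for c in calls]}
    )
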