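"""Coding-consequence nomenclature and ACMG evidence combination.

Computes HGVS protein consequences for single-base coding deletions
(``p.<Aa><N><Bb>fs*<K>``, with the stop counted as position K in the shifted
frame) and combines ACMG/AMP evidence codes into the standard five-tier
classification using the published combining rules.
"""

from __future__ import annotations

import re

from Bio.Seq import Seq
from Bio.SeqUtils import seq3


def codon_index(cds_position: int) -> int:
    """Codon number containing a 1-based CDS nucleotide position (ceil(p/3))."""
    if cds_position < 1:
        raise ValueError("CDS position must be >= 1")
    return (int(cds_position) + 2) // 3


def _translate(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        return ""
    return str(Seq(nt).translate())


def frameshift_consequence(cds_sequence: str, cds_position: int) -> str:
    """HGVS protein consequence of a single-base deletion in a CDS.

    Translates the reference codon at the deletion, re-translates the
    shifted frame from that codon, and names the first residue that truly
    differs (so a deletion inside a repeat never reports the unchanged
    residue). K in ``fs*K`` is the stop's position in the new reading frame
    counting the first changed residue as 1; no downstream stop gives
    ``fs*?``; an immediate stop at the changed codon is reported as
    ``p.<Aa><N>*``.
    """
    cds = str(cds_sequence).upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if not re.fullmatch(r"[ACGT]+", cds):
        raise ValueError("CDS may contain only ACGT")
    if not (1 <= cds_position <= len(cds)):
        raise ValueError("deletion position outside the CDS")

    ci = codon_index(cds_position)
    orig_prot = _translate(cds)
    mutant = cds[: cds_position - 1] + cds[cds_position:]
    new_tail = _translate(mutant[(ci - 1) * 3 :])
    orig_tail = orig_prot[ci - 1 :]

    # first genuinely differing residue in the shifted frame
    d = None
    for k in range(len(new_tail)):
        if k >= len(orig_tail) or new_tail[k] != orig_tail[k]:
            d = k
            break
    if d is None:
        # shifted frame reproduces the original tail but runs off the end
        # (stop codon lost): no describable frameshift product
        return "p.?"

    ref_aa = orig_tail[d] if d < len(orig_tail) else None
    if ref_aa is None or ref_aa == "*":
        # change begins at/after the reference stop: extension, out of scope
        return "p.?"
    n = ci + d
    new_aa = new_tail[d]
    if new_aa == "*":
        return f"p.{seq3(ref_aa)}{n}*"
    stop_off = new_tail.find("*", d)
    k_str = str(stop_off - d + 1) if stop_off != -1 else "?"
    return f"p.{seq3(ref_aa)}{n}{seq3(new_aa)}fs*{k_str}"


# ---------------------------------------------------------------------------
# ACMG combining rules
# ---------------------------------------------------------------------------

_ACMG_CODES = (
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

PATHOGENIC = "Pathogenic"
LIKELY_PATHOGENIC = "Likely pathogenic"
VUS = "Uncertain significance"
LIKELY_BENIGN = "Likely benign"
BENIGN = "Benign"


def combine_acmg(evidence: set[str] | list[str] | tuple[str, ...]) -> str:
    """Five-tier classification from ACMG/AMP evidence codes.

    Implements the published combining rules; conflicting pathogenic and
    benign evidence, or insufficient evidence, yields uncertain
    significance. Unknown codes are rejected.
    """
    codes = {str(c).upper() for c in evidence}
    unknown = codes - _ACMG_CODES
    if unknown:
        raise ValueError(f"unknown ACMG code(s): {sorted(unknown)}")

    pvs = int("PVS1" in codes)
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = int("BA1" in codes)
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba == 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return VUS
    if pathogenic:
        return PATHOGENIC
    if likely_pathogenic:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return VUS
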