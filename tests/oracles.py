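"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: consequence calls
come from translating the entire wild-type and mutant CDS, and exact
rank-sum p-values from enumerating every group assignment.
"""
import itertools

import numpy as np
from Bio.Seq import Seq
from scipy import stats as sps

from oatmap import Consequence

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def translation_oracle(annotator, transcript, variant):
    """Consequence and residue from full WT-vs-mutant CDS translation.

    Returns (consequence, residue or None); residue is the 1-based index
    of the first differing amino acid.
    """
    cds_wt = annotator.cds_sequence(transcript)
    pos0 = variant.pos - 1
    offsets = []
    cum = 0
    for s, e in transcript.cds:
        if s <= pos0 < e:
            offsets.append(cum + pos0 - s)
        cum += e - s
    assert offsets, "oracle called with a non-CDS variant"
    off = offsets[0]
    alt = variant.alt
    if transcript.strand == "-":
        off = len(cds_wt) - 1 - off
        alt = alt.translate(COMPLEMENT)
    cds_mut = cds_wt[:off] + alt + cds_wt[off + 1 :]
    prot_wt = str(Seq(cds_wt).translate())
    prot_mut = str(Seq(cds_mut).translate())
    if off < 3 and cds_mut[:3] != "ATG":
        return Consequence.START_LOST, 1
    if prot_wt == prot_mut:
        return Consequence.SYNONYMOUS, None
    residue = next(i + 1 for i, (a, b) in enumerate(zip(prot_wt, prot_mut)) if a != b)
    if prot_mut[residue - 1] == "*":
        return Consequence.STOP_GAINED, residue
    if prot_wt[residue - 1] == "*":
        return Consequence.STOP_LOST, residue
    return Consequence.MISSENSE, residue


def enumeration_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all C(n, n_x) group
    assignments (midranks for ties; doubled smaller tail, capped at 1)."""
    combined = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = sps.rankdata(combined)
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    sums = np.asarray([sum(c) for c in itertools.combinations(ranks, n_x)])
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return min(1.0, 2 * min(p_le, p_ge))
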