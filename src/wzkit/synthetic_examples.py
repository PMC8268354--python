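"""Synthetic reference-like objects for examples and tests.

The gene built here is a synthetic reconstruction of the W-linked banf2
variant's published genomic organisation: three exons of 119, 127 and 231 bp
separated by introns of 1002 and 668 bp (transcript 477 bp, genomic span
2147 bp), canonical GT..AG splice sites, a 270 bp CDS encoding 89 residues,
and the documented 3'-UTR tail of exon 3 carrying two overlappable AATAAA
polyadenylation signals.  All sequence outside those documented features is
random filler, so only the structure — not the bases — should be compared
against real data.
"""

from __future__ import annotations

import numpy as np

from .genemodel import GeneModel

#: documented tail of exon 3: last coding codon (CTG), the TGA stop, and the
#: 3'UTR with two AATAAA polyadenylation signals
EXON3_TAIL = ("CTGTGAGGCCCCGCCCCCTTTACCTGAGAGGCACCTCTCAGCTGATTATGTGCTGAGCATG"
              "AATAAAACATAAATAAAGTTTGTGTGCCGGAG")

EXON_LENGTHS = [119, 127, 231]
INTRON_LENGTHS = [1002, 668]

# codons free of stop triplets, for random coding filler
_SAFE_CODONS = [a + b + c
                for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS, size=n))


def banf2w_like_gene(seed: int = 0) -> GeneModel:
    """Build the synthetic W-variant gene model (see module docstring).

    The CDS starts one base into exon 2 and ends with the TGA inside the
    documented exon-3 tail: 270 bp, 89 residues.
    """
    rng = np.random.default_rng(seed)
    exon1 = _random_bases(rng, EXON_LENGTHS[0])
    # exon 2: 1 leading UTR base, ATG, then 41 stop-free codons (127 bp)
    exon2 = _random_bases(rng, 1) + "ATG" + _random_codons(rng, 41)
    # exon 3: 46 stop-free codons, then the documented tail (231 bp total)
    n_coding3 = (EXON_LENGTHS[2] - len(EXON3_TAIL)) // 3
    exon3 = _random_codons(rng, n_coding3) + EXON3_TAIL
    assert len(exon2) == EXON_LENGTHS[1] and len(exon3) == EXON_LENGTHS[2]
    introns = ["GT" + _random_bases(rng, n - 4) + "AG" for n in INTRON_LENGTHS]
    sequence = exon1 + introns[0] + exon2 + introns[1] + exon3
    cds_start = EXON_LENGTHS[0] + 2  # transcript coordinate of the ATG
    cds_end = cds_start + 270 - 1
    return GeneModel("banf2w_like", EXON_LENGTHS, INTRON_LENGTHS,
                     sequence=sequence, cds=(cds_start, cds_end))
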