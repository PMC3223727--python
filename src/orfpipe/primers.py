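"""Gateway-tailed ORF-specific primer design.

For each CDS a forward primer is anchored exactly at the A of the ATG
start codon and a reverse primer at the codon immediately before the
stop codon (so the amplicon is the CDS minus its stop, ready for
recombinational cloning in frame with vector tags). Gene-specific parts
are grown from 18 to 30 nt until the melting temperature falls in the
55-65 degC window; each primer then gets a Gateway attB adapter tail
(B1.1 forward, B2.1 reverse) at its 5' end.

Tm of the gene-specific part uses the nearest-neighbor model
(SantaLucia unified parameters, 50 mM Na+, 500 nM primer) by default,
with the simple Wallace 2+4 rule available as a fallback. The shipped
B1.1/B2.1 tails are the standard 12-nt partial attB adapter sequences;
confirm them against your cloning system before ordering oligos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple

import pandas as pd
from Bio.SeqUtils import MeltingTemp as mt

from .records import SequenceRecord, reverse_complement

# standard 12-nt partial attB adapters (two-step Gateway PCR); overridable
ATTB1_1_TAIL = "AAAAAGCAGGCT"
ATTB2_1_TAIL = "AGAAAGCTGGGT"

STOP_CODONS = ("TAA", "TAG", "TGA")

TmFormula = Literal["nn", "wallace"]


class PrimerDesignError(ValueError):
    """Raised when no gene-specific length satisfies the Tm window."""

    def __init__(self, orf_id: str, reason: str):
        self.orf_id = orf_id
        super().__init__(f"{orf_id}: {reason}")


@dataclass(frozen=True)
class PrimerPair:
    orf_id: str
    forward_full: str
    reverse_full: str
    forward_gs_len: int
    reverse_gs_len: int
    forward_tm: float
    reverse_tm: float
    tm_formula: TmFormula = "nn"


def melting_temperature(seq: str, formula: TmFormula = "nn") -> float:
    """Tm (degC) of a primer under the configured formula."""
    if formula == "nn":
        return float(mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=500, dnac2=0))
    if formula == "wallace":
        return float(mt.Tm_Wallace(seq))
    raise ValueError(f"unknown Tm formula {formula!r}")


def _validate_cds(cds: SequenceRecord) -> None:
    if cds.alphabet != "nucleotide":
        raise PrimerDesignError(cds.id, "CDS must be a nucleotide record")
    if len(cds) < 60:
        raise PrimerDesignError(cds.id, f"CDS too short ({len(cds)} nt)")
    if len(cds) % 3 != 0:
        raise PrimerDesignError(cds.id, "CDS length not divisible by 3")
    if not cds.residues.startswith("ATG"):
        raise PrimerDesignError(cds.id, "CDS does not start with ATG")
    if cds.residues[-3:] not in STOP_CODONS:
        raise PrimerDesignError(cds.id, "CDS does not end with a stop codon")


def _pick_gene_specific(
    template: str,
    orf_id: str,
    which: str,
    tm_min: float,
    tm_max: float,
    len_range: Tuple[int, int],
    formula: TmFormula,
) -> Tuple[str, float]:
    """Shortest prefix of ``template`` in len_range with Tm in the window."""
    for length in range(len_range[0], min(len_range[1], len(template)) + 1):
        candidate = template[:length]
        tm = melting_temperature(candidate, formula)
        if tm_min <= tm <= tm_max:
            return candidate, tm
    raise PrimerDesignError(
        orf_id,
        f"no {which} gene-specific length in {len_range} reaches "
        f"Tm in [{tm_min}, {tm_max}] degC",
    )


def design_orf_primers(
    cds: SequenceRecord,
    b1_tail: str = ATTB1_1_TAIL,
    b2_tail: str = ATTB2_1_TAIL,
    tm_min: float = 55.0,
    tm_max: float = 65.0,
    len_range: Tuple[int, int] = (18, 30),
    tm_formula: TmFormula = "nn",
) -> PrimerPair:
    """Design the Gateway-tailed forward/reverse primer pair for one CDS.

    Raises :class:`PrimerDesignError` (naming the ORF) when the CDS is
    malformed or no candidate length meets the Tm window.
    """
    _validate_cds(cds)
    forward_gs, forward_tm = _pick_gene_specific(
        cds.residues, cds.id, "forward", tm_min, tm_max, len_range, tm_formula
    )
    # reverse primer anchors at the codon immediately before the stop:
    # its template is the reverse complement of the CDS minus the stop codon
    body = SequenceRecord(cds.id, cds.residues[:-3], "nucleotide")
    rev_template = reverse_complement(body).residues
    reverse_gs, reverse_tm = _pick_gene_specific(
        rev_template, cds.id, "reverse", tm_min, tm_max, len_range, tm_formula
    )
    return PrimerPair(
        orf_id=cds.id,
        forward_full=b1_tail.upper() + forward_gs,
        reverse_full=b2_tail.upper() + reverse_gs,
        forward_gs_len=len(forward_gs),
        reverse_gs_len=len(reverse_gs),
        forward_tm=forward_tm,
        reverse_tm=reverse_tm,
        tm_formula=tm_formula,
    )


def design_many(
    cds_list: Sequence[SequenceRecord], **kwargs
) -> Tuple[List[PrimerPair], List[Tuple[str, str]]]:
    """Design primers for a CDS collection; (pairs, [(orf_id, failure reason)])."""
    pairs: List[PrimerPair] = []
    failures: List[Tuple[str, str]] = []
    for cds in cds_list:
        try:
            pairs.append(design_orf_primers(cds, **kwargs))
        except PrimerDesignError as exc:
            failures.append((cds.id, str(exc)))
    return pairs, failures


def primer_table(
    pairs: Sequence[PrimerPair], failures: Sequence[Tuple[str, str]] = ()
) -> pd.DataFrame:
    rows = [
        {
            "orf_id": p.orf_id,
            "forward_full": p.forward_full,
            "reverse_full": p.reverse_full,
            "forward_tm": round(p.forward_tm, 2),
            "reverse_tm": round(p.reverse_tm, 2),
            "tm_formula": p.tm_formula,
            "status": "ok",
        }
        for p in pairs
    ] + [
        {
            "orf_id": orf_id,
            "forward_full": "",
            "reverse_full": "",
            "forward_tm": float("nan"),
            "reverse_tm": float("nan"),
            "tm_formula": "",
            "status": f"failed: {reason}",
        }
        for orf_id, reason in failures
    ]
    return pd.DataFrame(
        sorted(rows, key=lambda r: r["orf_id"]),
        columns=[
            "orf_id",
            "forward_full",
            "reverse_full",
            "forward_tm",
            "reverse_tm",
            "tm_formula",
            "status",
        ],
    )
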