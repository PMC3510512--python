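"""Validation-arithmetic utilities: efficiency-corrected ΔΔCq and exact
in-silico PCR.

These mirror the bookkeeping used to confirm screen hits by RT-qPCR:
relative quantification with per-assay amplification efficiencies
(Pfaffl's ratio), and amplicon-size prediction by exact primer matching
on a template transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import AmbiguousProductError, NoProductError, ValidationError

_DNA = set("ACGT")


def _check_efficiency(e: float, label: str) -> float:
    if not 1.0 < e <= 2.0:
        raise ValidationError(
            f"{label}={e}: per-cycle efficiency must be in (1, 2] "
            "(use efficiency_from_percent for percentage inputs)"
        )
    return float(e)


def efficiency_from_percent(pct: float) -> float:
    """Convert a percent efficiency (100% = perfect doubling) to the
    per-cycle fold: E = 1 + pct/100."""
    return _check_efficiency(1.0 + pct / 100.0, "efficiency")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Efficiencies and ΔCq values for one relative quantification.

    ΔCq is Cq(control) - Cq(treated), in cycles, for the target and the
    reference gene; efficiencies are per-cycle folds in (1, 2].
    """

    e_target: float
    e_reference: float
    dcq_target: float
    dcq_reference: float

    def __post_init__(self):
        _check_efficiency(self.e_target, "e_target")
        _check_efficiency(self.e_reference, "e_reference")


def pfaffl_ratio(m: QpcrMeasurement) -> float:
    """Relative expression fold: E_target^ΔCq_target / E_ref^ΔCq_ref.

    With both efficiencies equal to 2 this reduces to the classic
    2^-ΔΔCq.
    """
    return m.e_target**m.dcq_target / m.e_reference**m.dcq_reference


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primer sequences, both written 5'->3'."""

    forward_seq: str
    reverse_seq: str

    def __post_init__(self):
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if not seq:
                raise ValidationError(f"{label} primer is empty")
            bad = set(seq.upper()) - _DNA
            if bad:
                raise ValidationError(
                    f"{label} primer contains non-ACGT characters {sorted(bad)}"
                )


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    forward_start: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def insilico_pcr(template: str, primers: PrimerPair) -> Amplicon:
    """Predict the PCR product by exact primer matching.

    The forward primer must match the template verbatim; the reverse
    primer binds where its reverse complement matches, downstream of the
    forward site.  The amplicon runs from the forward primer's 5' end
    through the reverse primer's 5' end (the last base of the
    reverse-complement match), inclusive — the standard product size.

    Raises :class:`NoProductError` when no productive placement exists
    and :class:`AmbiguousProductError` (listing all lengths) when more
    than one does.  Exact matching only: this is a bookkeeping check,
    not a primer-design tool.
    """
    if not template:
        raise ValidationError("empty template")
    template = template.upper()
    fwd = primers.forward_seq.upper()
    rev_rc = str(Seq(primers.reverse_seq.upper()).reverse_complement())
    fwd_hits = _find_all(template, fwd)
    rev_hits = _find_all(template, rev_rc)
    products = [
        (f, r)
        for f in fwd_hits
        for r in rev_hits
        if r >= f  # reverse site downstream of (or coincident with) forward 5' end
    ]
    if not products:
        raise NoProductError(
            "no product: forward %sfound, reverse-complement %sfound"
            % ("" if fwd_hits else "not ", "" if rev_hits else "not ")
        )
    if len(products) > 1:
        raise AmbiguousProductError(
            [r + len(rev_rc) - f for f, r in products]
        )
    f, r = products[0]
    return Amplicon(sequence=template[f : r + len(rev_rc)], forward_start=f)
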