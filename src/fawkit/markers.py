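"""Diagnostic-site location and strain/haplotype classification.

Fall armyworm host strains are distinguished by single-nucleotide
markers in two genes:

* mitochondrial COI: the base at site 1164 (counted from the predicted
  translational start) separates rice-strain (T) from corn-strain
  (A or G); combined with site 1287 (A or G) the corn strain splits
  into four haplotypes h1 (A,A), h2 (A,G), h3 (G,A) and h4 (G,G).
* Z-linked Tpi: the base at position 183 of exon 4 gives the
  corn-strain allele TpiC (C), the rice-strain allele TpiR (T), or a
  male heterozygote TpiH (C/T double peak, encoded IUPAC Y).

The marker positions are configured in :class:`MarkerOffsets` as
offsets within the bundled amplicon references, so synthetic reference
sequences need not reproduce genomic numbering; the attribute names
keep the field's site names (1164, 1287, Tpi183).

Species identification uses the 259-bp COIB segment shared across
Spodoptera reference records (COIB259): the query is assigned to the
panel entry at minimum Tamura–Nei (TN93) distance, with a ceiling above
which no confident assignment is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import AMBIGUITY_CODES, SpecimenRecord, read_fasta

__all__ = [
    "MarkerOffsets",
    "CoiCall",
    "TpiCall",
    "MarkerCall",
    "ReferencePanel",
    "ReferenceSet",
    "SegmentHit",
    "locate_segment",
    "call_coi_sites",
    "classify_coi",
    "call_tpi183",
    "detect_intron_frameshift_het",
    "identify_species",
    "classify_specimen",
    "classify_dataset",
    "load_default_references",
    "calls_to_frame",
]

COI_CLASSES = ("RS", "h1", "h2", "h3", "h4")
TPI_CLASSES = ("TpiC", "TpiR", "TpiH")


@dataclass(frozen=True)
class MarkerOffsets:
    """Marker coordinates, as 0-based offsets within the COIB and Tpi
    amplicon references.  Windows are half-open ``(start, end)``."""

    coib259_window: tuple[int, int]
    coib296_window: tuple[int, int]
    pos_1164: int
    pos_1287: int
    tpie4i4_window: tuple[int, int]
    pos_tpi183: int
    tpi_intron_window: tuple[int, int]

    def __post_init__(self):
        if not self.pos_1164 < self.pos_1287:
            raise ValueError("pos_1164 must precede pos_1287")
        for pos, (lo, hi), name in (
            (self.pos_1164, self.coib296_window, "pos_1164/coib296"),
            (self.pos_1287, self.coib296_window, "pos_1287/coib296"),
            (self.pos_1164, self.coib259_window, "pos_1164/coib259"),
            (self.pos_1287, self.coib259_window, "pos_1287/coib259"),
            (self.pos_tpi183, self.tpie4i4_window, "pos_tpi183/tpie4i4"),
        ):
            if not lo <= pos < hi:
                raise ValueError(f"{name}: position {pos} outside window ({lo},{hi})")
        ilo, ihi = self.tpi_intron_window
        tlo, thi = self.tpie4i4_window
        if not (tlo <= ilo < ihi <= thi):
            raise ValueError("intron window must lie inside the Tpie4i4 window")


@dataclass
class SegmentHit:
    """Result of anchoring a reference window inside an amplicon read."""

    sequence: str  #: the amplicon subsequence aligned to the window
    offset: int  #: 0-based start of the window within the amplicon
    identity: float  #: fraction of identical positions
    ok: bool  #: identity >= the location threshold


@dataclass
class CoiCall:
    base_1164: str
    base_1287: str
    coi_class: str  # RS / h1..h4 / unclassified
    flags: list[str] = field(default_factory=list)


@dataclass
class TpiCall:
    base_183: str
    tpi_class: str  # TpiC / TpiR / TpiH / unclassified
    frameshift_het: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class MarkerCall:
    """Per-specimen classification across both loci."""

    specimen_id: str
    site_id: str
    coi: CoiCall | None
    tpi: TpiCall | None

    @property
    def coi_class(self) -> str:
        return self.coi.coi_class if self.coi else "no_segment"

    @property
    def tpi_class(self) -> str:
        return self.tpi.tpi_class if self.tpi else "no_segment"


@dataclass
class ReferencePanel:
    """COIB259 reference panel for species identification."""

    entries: list[tuple[str, str]]
    consensus_cs: str
    consensus_rs: str

    def __post_init__(self):
        lengths = {len(s) for _, s in self.entries}
        lengths |= {len(self.consensus_cs), len(self.consensus_rs)}
        if len(lengths) != 1:
            raise ValueError(f"panel sequences not equal length: {sorted(lengths)}")

    @property
    def segment_length(self) -> int:
        return len(self.consensus_cs)


@dataclass
class ReferenceSet:
    """Everything classification needs: the COIB and Tpi reference
    amplicons (corn-strain backbones used for segment location), the
    species panel, and the marker offsets."""

    coib_amplicon_cs: str
    coib_amplicon_rs: str
    tpi_amplicon_c: str
    tpi_amplicon_r: str
    panel: ReferencePanel
    offsets: MarkerOffsets


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def locate_segment(
    amplicon: str,
    reference: str,
    window: tuple[int, int],
    min_identity: float = 0.80,
) -> SegmentHit:
    """Anchor ``reference[window]`` inside ``amplicon`` by exhaustive
    ungapped scan, returning the best-identity placement.

    Replaces a multiple-alignment step: amplicons are already curated,
    so a sliding exact-identity scan over all offsets suffices.  A best
    identity below ``min_identity`` marks the hit not-ok and the
    specimen is excluded from downstream calls.
    """
    lo, hi = window
    target = reference[lo:hi]
    w = len(target)
    if len(amplicon) < w:
        raise ValueError(
            f"amplicon length {len(amplicon)} shorter than window length {w}"
        )
    amp = _to_bytes(amplicon.upper())
    tgt = _to_bytes(target.upper())
    views = np.lib.stride_tricks.sliding_window_view(amp, w)
    identities = (views == tgt).mean(axis=1)
    best = int(np.argmax(identities))  # ties -> leftmost placement
    ident = float(identities[best])
    return SegmentHit(
        sequence=amplicon[best : best + w].upper(),
        offset=best,
        identity=ident,
        ok=ident >= min_identity,
    )


def call_coi_sites(segment: str, offsets: MarkerOffsets) -> tuple[str, str]:
    """Read the bases at the two COI diagnostic sites from a located
    COIB296 window (as returned by :func:`locate_segment`)."""
    lo, _ = offsets.coib296_window
    return (
        segment[offsets.pos_1164 - lo].upper(),
        segment[offsets.pos_1287 - lo].upper(),
    )


_COI_TABLE = {
    ("T", "A"): "RS",
    ("A", "A"): "h1",
    ("A", "G"): "h2",
    ("G", "A"): "h3",
    ("G", "G"): "h4",
}


def classify_coi(base_1164: str, base_1287: str) -> CoiCall:
    """Map the diagnostic base pair to a COI class.

    T at 1164 defines the rice strain; A/G at 1164 crossed with A/G at
    1287 give the corn-strain haplotypes h1–h4.  The combination (T, G)
    was never observed in the field data this scheme comes from: the
    T1164-defines-RS rule stays primary and the call is RS with a
    data-quality warning.  Bases outside the observed alphabets (D at
    1164, R at 1287), including N or gaps, are unclassified.
    """
    b1, b2 = base_1164.upper(), base_1287.upper()
    flags: list[str] = []
    if b1 not in "AGT":
        return CoiCall(b1, b2, "unclassified", [f"non-D IUPAC base at 1164: {b1}"])
    if b2 not in "AG":
        return CoiCall(b1, b2, "unclassified", [f"non-R IUPAC base at 1287: {b2}"])
    if (b1, b2) == ("T", "G"):
        return CoiCall(b1, b2, "RS", ["T1164 with G1287: combination never observed"])
    return CoiCall(b1, b2, _COI_TABLE[(b1, b2)], flags)


def call_tpi183(segment: str, offsets: MarkerOffsets) -> TpiCall:
    """Classify the Tpi genotype from the base at exon-4 position 183
    of a located Tpie4i4 window: C -> TpiC, T -> TpiR, Y (C/T double
    peak) -> TpiH; anything else is unclassified."""
    lo, _ = offsets.tpie4i4_window
    idx = offsets.pos_tpi183 - lo
    if idx >= len(segment):
        return TpiCall("", "unclassified", flags=["site 183 not covered"])
    base = segment[idx].upper()
    table = {"C": "TpiC", "T": "TpiR", "Y": "TpiH"}
    if base in table:
        return TpiCall(base, table[base])
    return TpiCall(base, "unclassified", flags=[f"unexpected base at Tpi183: {base}"])


def detect_intron_frameshift_het(
    segment: str, offsets: MarkerOffsets, min_run: int = 6
) -> bool:
    """Flag likely intron frameshift heterozygotes.

    A male heterozygous for an intron indel shows overlapping
    chromatograph traces from the indel onward; after base calling this
    surfaces as a long run of ambiguity codes.  The desk-scale proxy:
    a run of >= ``min_run`` consecutive ambiguity codes beginning inside
    the intron.  Flagged records are excluded from haplotype-network
    input (their downstream sequence is not a real haplotype).
    """
    seg_lo, _ = offsets.tpie4i4_window
    ilo, ihi = offsets.tpi_intron_window
    start, end = ilo - seg_lo, ihi - seg_lo
    run = 0
    for i in range(start, min(end, len(segment))):
        if segment[i].upper() in AMBIGUITY_CODES:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


@dataclass
class SpeciesAssignment:
    labels: list[str]  #: best-matching panel taxa (more than one on a tie)
    distance: float  #: TN93 distance to the best match
    confident: bool  #: distance below the assignment ceiling


def identify_species(
    query_coib259: str,
    panel: ReferencePanel,
    max_distance: float = 0.10,
    tie_tol: float = 1e-12,
) -> SpeciesAssignment:
    """Assign a COIB259 query to the nearest panel taxon by TN93
    distance; ties are reported as multiple labels, and a minimum
    distance above ``max_distance`` substitutions/site yields a
    non-confident assignment."""
    from .phylo import tn93_distance

    if len(query_coib259) != panel.segment_length:
        raise ValueError(
            f"query length {len(query_coib259)} != panel segment length "
            f"{panel.segment_length}"
        )
    dists = [
        (label, tn93_distance(query_coib259, seq)) for label, seq in panel.entries
    ]
    dmin = min(d for _, d in dists)
    labels = [label for label, d in dists if d <= dmin + tie_tol]
    return SpeciesAssignment(labels=labels, distance=dmin, confident=dmin <= max_distance)


def classify_specimen(
    record: SpecimenRecord,
    refs: ReferenceSet,
    min_identity: float = 0.80,
    frameshift_min_run: int = 6,
    assume_anchored: bool = False,
) -> MarkerCall:
    """Run the full per-specimen classification.

    For each locus present: anchor the diagnostic window in the
    amplicon, then apply the site rules.  A locus whose segment cannot
    be located (identity below threshold) yields ``None`` for that call
    and the specimen drops out of that locus's denominators.

    ``assume_anchored`` skips the scan and takes the amplicon to start
    at reference position 0 (valid for reads already trimmed to the
    reference amplicon, e.g. simulator output); the identity check is
    still applied at offset 0.
    """
    coi_call: CoiCall | None = None
    tpi_call: TpiCall | None = None
    offs = refs.offsets

    coib = record.sequences.get("COIB")
    if coib is not None:
        hit = _anchor(coib, refs.coib_amplicon_cs, offs.coib296_window,
                      min_identity, assume_anchored)
        if not hit.ok:
            # corn-strain backbone missed; the rice-strain backbone may anchor
            hit_rs = _anchor(coib, refs.coib_amplicon_rs, offs.coib296_window,
                             min_identity, assume_anchored)
            if hit_rs.identity > hit.identity:
                hit = hit_rs
        if hit.ok:
            b1164, b1287 = call_coi_sites(hit.sequence, offs)
            coi_call = classify_coi(b1164, b1287)

    tpi = record.sequences.get("TPI")
    if tpi is not None:
        hit = _anchor(tpi, refs.tpi_amplicon_c, offs.tpie4i4_window,
                      min_identity, assume_anchored)
        if hit.ok:
            tpi_call = call_tpi183(hit.sequence, offs)
            tpi_call.frameshift_het = detect_intron_frameshift_het(
                hit.sequence, offs, min_run=frameshift_min_run
            )

    return MarkerCall(
        specimen_id=record.specimen_id,
        site_id=record.site_id,
        coi=coi_call,
        tpi=tpi_call,
    )


def _anchor(amplicon, reference, window, min_identity, assume_anchored) -> SegmentHit:
    if assume_anchored:
        lo, hi = window
        seg = amplicon[lo:hi]
        if len(seg) < hi - lo:
            return SegmentHit(seg, lo, 0.0, False)
        a, b = _to_bytes(seg.upper()), _to_bytes(reference[lo:hi].upper())
        ident = float((a == b).mean())
        return SegmentHit(seg, lo, ident, ident >= min_identity)
    return locate_segment(amplicon, reference, window, min_identity)


def classify_dataset(
    records: Iterable[SpecimenRecord],
    refs: ReferenceSet,
    **kwargs,
) -> list[MarkerCall]:
    """Classify every specimen; see :func:`classify_specimen`."""
    return [classify_specimen(r, refs, **kwargs) for r in records]


def calls_to_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    """Tabulate marker calls for export (one row per specimen)."""
    rows = []
    for c in calls:
        flags = []
        if c.coi:
            flags += c.coi.flags
        if c.tpi:
            flags += c.tpi.flags
        rows.append(
            {
                "specimen_id": c.specimen_id,
                "site_id": c.site_id,
                "coi_class": c.coi_class,
                "tpi_class": c.tpi_class,
                "frameshift_het": bool(c.tpi.frameshift_het) if c.tpi else False,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "site_id", "coi_class", "tpi_class",
            "frameshift_het", "flags",
        ],
    )


def _read_offsets_cfg(text: str) -> MarkerOffsets:
    kv: dict[str, int] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = int(val.strip())
    return MarkerOffsets(
        coib259_window=(kv["coib259_start"], kv["coib259_end"]),
        coib296_window=(kv["coib296_start"], kv["coib296_end"]),
        pos_1164=kv["pos_1164"],
        pos_1287=kv["pos_1287"],
        tpie4i4_window=(kv["tpie4i4_start"], kv["tpie4i4_end"]),
        pos_tpi183=kv["pos_tpi183"],
        tpi_intron_window=(kv["tpi_intron_start"], kv["tpi_intron_end"]),
    )


def load_default_references() -> ReferenceSet:
    """Load the bundled synthetic reference set.

    The shipped panel and amplicons are synthetic stand-ins that honour
    every diagnostic relationship the classification relies on (CS/RS
    differ at the 1164 site, the corn-strain backbone carries the h
    alphabet, two panel taxa are deliberately identical); they are not
    the field consensus sequences.
    """
    data = resources.files("fawkit.data")
    offsets = _read_offsets_cfg((data / "marker_offsets.cfg").read_text())

    def _as_dict(fname):
        text = (data / fname).read_text()
        recs = {}
        name, chunks = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name is not None:
                    recs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line.strip():
                chunks.append(line.strip().upper())
        if name is not None:
            recs[name] = "".join(chunks)
        return recs

    panel_seqs = _as_dict("synthetic_coib259_panel.fasta")
    amps = _as_dict("synthetic_reference_amplicons.fasta")
    consensus_cs = panel_seqs.pop("S_frugiperda_CS_consensus")
    consensus_rs = panel_seqs.pop("S_frugiperda_RS_consensus")
    panel = ReferencePanel(
        entries=[("S_frugiperda_CS_consensus", consensus_cs),
                 ("S_frugiperda_RS_consensus", consensus_rs)]
        + list(panel_seqs.items()),
        consensus_cs=consensus_cs,
        consensus_rs=consensus_rs,
    )
    return ReferenceSet(
        coib_amplicon_cs=amps["COIB_CS"],
        coib_amplicon_rs=amps["COIB_RS"],
        tpi_amplicon_c=amps["TPI_C"],
        tpi_amplicon_r=amps["TPI_R"],
        panel=panel,
        offsets=offsets,
    )
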