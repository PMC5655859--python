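"""In-silico nick-label reference maps.

A nicking endonuclease cuts one strand of double-stranded DNA wherever its
recognition motif occurs; the nick is fluorescently labeled, so each motif
occurrence becomes a landmark ("label") on the molecule backbone.  This
module builds the reference side of that picture: ordered label positions
per contig and per enzyme channel, either by in-silico digestion of a
nucleotide sequence or by direct homogeneous-Poisson placement (which lets
the rest of the pipeline run without any real sequence).  It also plants
ground-truth structural variants into a map and round-trips maps through a
small tab-separated CMAP dialect.

Coordinates: label positions are 1-based bp (the convention of the emitted
CMAP files and of :func:`digest_sequence`); SV edit intervals are 0-based
half-open ``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EnzymeSpec",
    "Contig",
    "ReferenceMap",
    "SVEdit",
    "SVTruth",
    "DEFAULT_ENZYMES",
    "digest_sequence",
    "find_fragile_sites",
    "poisson_reference",
    "apply_sv_to_map",
    "read_cmap",
    "write_cmap",
    "read_fasta",
]

# IUPAC nucleotide codes -> regex character classes
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A nicking endonuclease: a short recognition motif on one strand.

    ``strand_convention`` controls whether occurrences of the motif's
    reverse complement (i.e. motif hits on the minus strand) also produce
    labels.  Real single-strand nicks are strand-specific, but on the
    imaged backbone a label is a label; both behaviors are exposed.
    """

    name: str
    recognition_motif: str
    strand_convention: bool = True

    def __post_init__(self) -> None:
        motif = self.recognition_motif.upper()
        if not motif:
            raise ValueError("recognition motif must be non-empty")
        bad = set(motif) - set(_IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.recognition_motif!r} contains non-IUPAC "
                f"characters: {sorted(bad)}"
            )
        object.__setattr__(self, "recognition_motif", motif)

    @property
    def motif_regex(self) -> str:
        return "".join(_IUPAC[c] for c in self.recognition_motif)


#: Catalog defaults; the recognition sequences are standard catalog values
#: and fully user-overridable.
DEFAULT_ENZYMES = {
    "Nt.BspQI": EnzymeSpec("Nt.BspQI", "GCTCTTC"),
    "Nb.BssSI": EnzymeSpec("Nb.BssSI", "CACGAG"),
}


@dataclass
class Contig:
    """One reference contig: length plus per-channel ordered label arrays."""

    contig_id: str
    length: float
    labels: list[np.ndarray]  # one sorted float array (bp, 1-based) per channel
    fragile_sites: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float)
    )

    def validate(self, n_channels: int) -> None:
        if len(self.labels) != n_channels:
            raise ValueError(
                f"contig {self.contig_id}: expected {n_channels} channels, "
                f"got {len(self.labels)}"
            )
        for ch, pos in enumerate(self.labels):
            if pos.size == 0:
                continue
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"contig {self.contig_id} channel {ch + 1}: label "
                    "positions must be strictly increasing"
                )
            if pos[0] < 1 or pos[-1] > self.length:
                raise ValueError(
                    f"contig {self.contig_id} channel {ch + 1}: label "
                    "positions out of contig bounds"
                )


@dataclass
class ReferenceMap:
    """Per-contig, per-enzyme ordered nick-label positions."""

    contigs: list[Contig]
    channel_enzymes: dict[int, EnzymeSpec]

    def __post_init__(self) -> None:
        n = self.n_channels
        for contig in self.contigs:
            contig.validate(n)

    @property
    def n_channels(self) -> int:
        return len(self.channel_enzymes)

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.contigs))

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(f"no contig {contig_id!r}")

    def copy(self) -> "ReferenceMap":
        return ReferenceMap(
            contigs=[
                Contig(
                    c.contig_id,
                    c.length,
                    [p.copy() for p in c.labels],
                    c.fragile_sites.copy(),
                )
                for c in self.contigs
            ],
            channel_enzymes=dict(self.channel_enzymes),
        )


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(_IUPAC)
    if bad:
        raise ValueError(
            f"sequence contains non-nucleotide characters: {sorted(bad)}"
        )
    return seq


def digest_sequence(seq: str, enzyme: EnzymeSpec) -> np.ndarray:
    """In-silico digest: 1-based start coordinates of motif occurrences.

    Plus-strand occurrences always label; minus-strand occurrences
    (reverse-complement motif hits) label when ``enzyme.strand_convention``
    is set.  Overlapping occurrences are all reported; the result is sorted
    and deduplicated.
    """
    seq = _check_sequence(seq)
    if len(seq) < len(enzyme.recognition_motif):
        return np.empty(0, dtype=float)
    pat = re.compile(f"(?=({enzyme.motif_regex}))")
    starts = {m.start() + 1 for m in pat.finditer(seq)}
    if enzyme.strand_convention:
        rc = EnzymeSpec(enzyme.name, _revcomp(enzyme.recognition_motif), False)
        pat_rc = re.compile(f"(?=({rc.motif_regex}))")
        starts |= {m.start() + 1 for m in pat_rc.finditer(seq)}
    return np.array(sorted(starts), dtype=float)


def find_fragile_sites(
    seq: str, enzyme: EnzymeSpec, window: float = 1000.0
) -> np.ndarray:
    """Midpoints of opposite-strand nick pairs closer than ``window`` bp.

    Nicks on complementary strands that are too close nick both strands and
    can break the double helix; these loci truncate molecules during
    simulation.
    """
    seq = _check_sequence(seq)
    pat = re.compile(f"(?=({enzyme.motif_regex}))")
    plus = np.array([m.start() + 1 for m in pat.finditer(seq)], dtype=float)
    rc_motif = _revcomp(enzyme.recognition_motif)
    rc_regex = "".join(_IUPAC[c] for c in rc_motif)
    minus = np.array(
        [m.start() + 1 for m in re.compile(f"(?=({rc_regex}))").finditer(seq)],
        dtype=float,
    )
    sites = []
    j = 0
    for p in plus:
        while j < minus.size and minus[j] < p - window:
            j += 1
        k = j
        while k < minus.size and minus[k] <= p + window:
            sites.append((p + minus[k]) / 2.0)
            k += 1
    return np.unique(np.array(sites, dtype=float))


def poisson_reference(
    length_bp: float,
    mean_spacing_bp: float,
    n_channels: int = 1,
    seed: int | np.random.SeedSequence = 0,
    contig_id: str = "synth0",
) -> ReferenceMap:
    """Reference map with labels from a homogeneous Poisson process.

    Each channel gets independent exponential inter-label spacings with the
    given mean.  Reproducible under the same seed.
    """
    if mean_spacing_bp <= 0:
        raise ValueError("mean spacing must be positive")
    if length_bp <= 2 * mean_spacing_bp:
        raise ValueError("length must exceed twice the mean spacing")
    rng = np.random.default_rng(seed)
    labels = []
    for _ in range(n_channels):
        # draw enough gaps in one shot, then trim
        n_guess = int(length_bp / mean_spacing_bp * 1.5) + 20
        gaps = rng.exponential(mean_spacing_bp, size=n_guess)
        pos = np.cumsum(gaps)
        while pos.size and pos[-1] < length_bp:
            extra = rng.exponential(mean_spacing_bp, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos < length_bp]
        labels.append(pos + 1.0)  # 1-based
    enzymes = {
        ch + 1: EnzymeSpec(f"synthetic{ch + 1}", "NNNNNN")
        for ch in range(n_channels)
    }
    contig = Contig(contig_id, float(length_bp), labels)
    return ReferenceMap([contig], enzymes)


@dataclass(frozen=True)
class SVEdit:
    """A planted structural variant, 0-based half-open interval on a contig.

    kinds:
      * ``deletion``  — remove [start, end); downstream shifts left.
      * ``duplication`` — tandem-duplicate [start, end) in place (a
        gain-of-material insertion); downstream shifts right.
      * ``inversion`` — mirror label positions within [start, end).
    """

    kind: str
    contig_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication", "inversion"):
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")

    @property
    def size(self) -> float:
        return self.end - self.start


@dataclass
class SVTruth:
    """Exact truth for one planted SV, in original reference coordinates."""

    kind: str
    contig_id: str
    start: float
    end: float
    size: float
    zygosity: str = "homozygous"

    @property
    def signed_size(self) -> float:
        if self.kind == "deletion":
            return -self.size
        if self.kind == "duplication":
            return +self.size
        return 0.0


def apply_sv_to_map(
    ref: ReferenceMap, edits: Sequence[SVEdit]
) -> tuple[ReferenceMap, list[SVTruth]]:
    """Plant SVs into a reference map; return the edited map plus truth.

    Edits must be non-overlapping (checked per contig).  Edits are applied
    right-to-left so earlier coordinates stay valid.  Truth records carry
    the original-reference coordinates and exact sizes.
    """
    by_contig: dict[str, list[SVEdit]] = {}
    for e in edits:
        by_contig.setdefault(e.contig_id, []).append(e)
    for cid, es in by_contig.items():
        es.sort(key=lambda e: e.start)
        for a, b in zip(es, es[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping edits on {cid}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        clen = ref.contig(cid).length
        if es[-1].end > clen:
            raise ValueError(f"edit exceeds contig {cid} length {clen}")

    out = ref.copy()
    truths: list[SVTruth] = []
    for cid, es in by_contig.items():
        contig = out.contig(cid)
        for e in reversed(es):  # right-to-left
            s, t = e.start, e.end
            size = e.size
            for ch in range(len(contig.labels)):
                pos = contig.labels[ch]
                if e.kind == "deletion":
                    inside = (pos > s) & (pos <= t)
                    kept = pos[~inside].copy()
                    kept[kept > t] -= size
                    contig.labels[ch] = kept
                elif e.kind == "duplication":
                    inside = pos[(pos > s) & (pos <= t)]
                    shifted = pos.copy()
                    shifted[shifted > t] += size
                    merged = np.concatenate([shifted, inside + size])
                    contig.labels[ch] = np.unique(merged)
                else:  # inversion
                    inside = (pos > s) & (pos <= t)
                    mirrored = pos.copy()
                    mirrored[inside] = s + t - pos[inside]
                    contig.labels[ch] = np.sort(mirrored)
            if e.kind == "deletion":
                contig.length -= size
            elif e.kind == "duplication":
                contig.length += size
            truths.append(SVTruth(e.kind, cid, s, t, size))
    # truths in left-to-right, stable order
    truths.sort(key=lambda t: (t.contig_id, t.start))
    # re-validate monotonicity
    for contig in out.contigs:
        contig.validate(out.n_channels)
    return out, truths


# ---------------------------------------------------------------- CMAP I/O

_CMAP_HEADER = "# omsv-cmap v1"
_CMAP_COLS = (
    "MapID\tContigLen\tNumSites\tSiteID\tChannel\tPosition\tHaplotype"
)


def write_cmap(path, ref: ReferenceMap, haplotypes: dict[str, int] | None = None) -> None:
    """Write a map in the tab-separated CMAP dialect.

    One row per label site; empty channels contribute no rows but the map
    still appears via its header comment.  Positions are emitted 1-based
    with 0.1 bp precision.
    """
    haplotypes = haplotypes or {}
    with open(path, "w") as fh:
        fh.write(_CMAP_HEADER + "\n")
        for ch, enz in sorted(ref.channel_enzymes.items()):
            fh.write(f"# channel {ch}: {enz.name} {enz.recognition_motif}\n")
        fh.write("#h " + _CMAP_COLS + "\n")
        for contig in ref.contigs:
            nsites = sum(p.size for p in contig.labels)
            hap = haplotypes.get(contig.contig_id, 0)
            site = 1
            for ch, pos in enumerate(contig.labels, start=1):
                for p in pos:
                    fh.write(
                        f"{contig.contig_id}\t{contig.length:.1f}\t{nsites}"
                        f"\t{site}\t{ch}\t{p:.1f}\t{hap}\n"
                    )
                    site += 1
            if nsites == 0:
                fh.write(
                    f"{contig.contig_id}\t{contig.length:.1f}\t0\t0\t0\t0.0"
                    f"\t{hap}\n"
                )


class CmapParseError(ValueError):
    pass


def read_cmap(path) -> tuple[ReferenceMap, dict[str, int]]:
    """Read the CMAP dialect back; returns (map, haplotype tags).

    Enforces the monotonicity invariant and names the offending line on
    malformed input.
    """
    channel_enzymes: dict[int, EnzymeSpec] = {}
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _CMAP_HEADER:
            raise CmapParseError(f"line 1: expected {_CMAP_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# channel "):
                body = line[len("# channel "):]
                ch_str, rest = body.split(":", 1)
                name, motif = rest.split()
                channel_enzymes[int(ch_str)] = EnzymeSpec(name, motif)
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise CmapParseError(
                    f"line {lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                cid = parts[0]
                clen = float(parts[1])
                ch = int(parts[4])
                pos = float(parts[5])
                hap = int(parts[6])
            except ValueError as exc:
                raise CmapParseError(f"line {lineno}: {exc}") from exc
            if cid not in rows:
                rows[cid] = {"length": clen, "chans": {}, "hap": hap}
                order.append(cid)
            if ch > 0:
                rows[cid]["chans"].setdefault(ch, []).append((lineno, pos))
    if not channel_enzymes:
        max_ch = max(
            (max(r["chans"], default=0) for r in rows.values()), default=0
        )
        channel_enzymes = {
            ch: EnzymeSpec(f"channel{ch}", "NNNNNN")
            for ch in range(1, max(max_ch, 1) + 1)
        }
    n_channels = max(channel_enzymes)
    contigs = []
    haps = {}
    for cid in order:
        r = rows[cid]
        labels = []
        for ch in range(1, n_channels + 1):
            entries = r["chans"].get(ch, [])
            pos = np.array([p for _, p in entries], dtype=float)
            if pos.size and np.any(np.diff(pos) <= 0):
                bad = entries[int(np.argmax(np.diff(pos) <= 0)) + 1][0]
                raise CmapParseError(
                    f"line {bad}: positions not strictly increasing "
                    f"(channel {ch} of map {cid})"
                )
            labels.append(pos)
        contigs.append(Contig(cid, r["length"], labels))
        haps[cid] = r["hap"]
    return ReferenceMap(contigs, channel_enzymes), haps


def read_fasta(path) -> Iterable[tuple[str, str]]:
    """Yield (contig_id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq)
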