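"""Simulation of labeled long DNA molecules from a reference map.

The generative chain mirrors the physical workflow: a long molecule is a
window of one haplotype; its true nick labels are observed with dropout
(labeling failure), interval-length-dependent sizing noise (nanochannel
stretch measurement), spurious labels (non-specific binding), an optical
resolution limit that fuses nearby labels, double-strand breaks at fragile
sites (opposite-strand nick pairs), and occasional chimeric joins of two
unrelated fragments.  Hidden origin truth is carried on every molecule so
downstream stages can be scored.

Seeding: one master seed; molecule ``k`` uses the substream
``default_rng([master, k])`` and is therefore identical regardless of how
molecules are batched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from omsv.reference_maps import ReferenceMap

__all__ = [
    "ErrorModel",
    "Placement",
    "Molecule",
    "RunSummary",
    "draw_molecule_lengths",
    "observe_molecule",
    "simulate_run",
    "effective_coverage",
    "write_bnx",
    "read_bnx",
]


@dataclass
class ErrorModel:
    """Parametric error model for molecule observation.

    sizing noise: the interval between consecutive retained labels is
    perturbed by a zero-mean Gaussian with variance
    ``sizing_sd0**2 + sizing_sd_scale * interval_length``.
    """

    sizing_sd0: float = 400.0            # bp
    sizing_sd_scale: float = 20.0        # variance bp^2 per bp of interval
    label_miss_rate: float = 0.10
    false_label_rate: float = 0.8        # expected spurious labels / 100 kb
    fragile_break_prob: float = 0.5
    fragile_window: float = 1000.0       # bp
    chimera_rate: float = 0.01
    resolution_limit: float = 1500.0     # bp

    def __post_init__(self) -> None:
        for name in ("label_miss_rate", "fragile_break_prob", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "sizing_sd0", "sizing_sd_scale", "false_label_rate",
            "fragile_window", "resolution_limit",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls) -> "ErrorModel":
        return cls(
            sizing_sd0=0.0, sizing_sd_scale=0.0, label_miss_rate=0.0,
            false_label_rate=0.0, fragile_break_prob=0.0, chimera_rate=0.0,
            resolution_limit=0.0,
        )

    def interval_sd(self, interval: float | np.ndarray) -> float | np.ndarray:
        return np.sqrt(self.sizing_sd0 ** 2 + self.sizing_sd_scale * np.asarray(interval))


@dataclass(frozen=True)
class Placement:
    """Where a molecule window comes from: haplotype, contig, span, strand."""

    haplotype: int
    contig_id: str
    start: float       # bp offset of window start on the contig (0-based)
    length: float      # bp
    strand: int        # +1 or -1

    @property
    def end(self) -> float:
        return self.start + self.length


@dataclass
class Molecule:
    """One simulated molecule: backbone plus per-channel observed labels."""

    molecule_id: int
    backbone_length: float
    labels: list[np.ndarray]             # per channel, bp from molecule start
    origin: Placement | None = None      # hidden truth
    chimera_of: Placement | None = None  # second fragment, if chimeric

    @property
    def n_labels(self) -> int:
        return int(sum(p.size for p in self.labels))

    def validate(self) -> None:
        for pos in self.labels:
            if pos.size == 0:
                continue
            if np.any(np.diff(pos) <= 0):
                raise ValueError("molecule labels must be strictly increasing")
            if pos[0] <= 0 or pos[-1] >= self.backbone_length:
                raise ValueError("labels must lie strictly inside the backbone")


@dataclass
class RunSummary:
    total_bases: float
    molecule_count: int
    map_rate: float
    genome_size: float

    @property
    def raw_coverage(self) -> float:
        return self.total_bases / self.genome_size

    @property
    def effective_coverage_fold(self) -> float:
        return effective_coverage(self.total_bases, self.genome_size, self.map_rate)


def effective_coverage(total_bases: float, genome_size: float, map_rate: float) -> float:
    """Effective fold coverage: total bases / genome size x map rate."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if total_bases < 0:
        raise ValueError("total bases must be non-negative")
    if not 0.0 <= map_rate <= 1.0:
        raise ValueError("map rate must be in [0, 1]")
    return total_bases / genome_size * map_rate


def draw_molecule_lengths(
    target_raw_coverage: float,
    haplotypes: Sequence[ReferenceMap],
    seed: int | Sequence[int],
    mean_length: float = 500_000.0,
    sigma_log: float = 0.40,
    min_length: float = 200_000.0,
) -> list[Placement]:
    """Draw molecule placements until raw coverage is met.

    Lengths are log-normal (parameterized by its mean on the natural scale)
    truncated below at ``min_length``; placements fall uniformly over
    haplotypes and, within a haplotype, over contigs weighted by length.
    Raw coverage is counted against the haploid genome size (haplotype 0).
    """
    if target_raw_coverage <= 0:
        raise ValueError("coverage must be positive")
    genome_size = haplotypes[0].total_length
    min_contig = min(c.length for h in haplotypes for c in h.contigs)
    if min_contig < min_length:
        raise ValueError(
            f"shortest contig ({min_contig:.0f} bp) is below the minimum "
            f"molecule length ({min_length:.0f} bp)"
        )
    mu = np.log(mean_length) - sigma_log ** 2 / 2.0
    rng = np.random.default_rng(seed)
    placements: list[Placement] = []
    total = 0.0
    target = target_raw_coverage * genome_size
    while total < target:
        length = float(rng.lognormal(mu, sigma_log))
        if length < min_length:
            continue
        hap = int(rng.integers(len(haplotypes)))
        contigs = haplotypes[hap].contigs
        weights = np.array([c.length for c in contigs])
        ci = int(rng.choice(len(contigs), p=weights / weights.sum()))
        contig = contigs[ci]
        length = min(length, contig.length)
        start = float(rng.uniform(0.0, contig.length - length))
        strand = 1 if rng.random() < 0.5 else -1
        placements.append(Placement(hap, contig.contig_id, start, length, strand))
        total += length
    return placements


def observe_molecule(
    haplotypes: Sequence[ReferenceMap],
    placement: Placement,
    model: ErrorModel,
    seed: int | Sequence[int],
    molecule_id: int = 0,
    chimera_partner: Placement | None = None,
) -> Molecule:
    """Observe one molecule under the error model.

    With all error rates zero the observed labels equal the true labels
    shifted by ``-placement.start`` (mirrored for minus-strand placements).
    """
    rng = np.random.default_rng(seed)
    ref = haplotypes[placement.haplotype]
    contig = ref.contig(placement.contig_id)
    if placement.start < 0 or placement.end > contig.length + 1e-6:
        raise ValueError("placement outside contig bounds")

    length = placement.length
    # fragile-site truncation: first broken fragile site (in molecule
    # orientation) cuts the molecule short
    if model.fragile_break_prob > 0 and contig.fragile_sites.size:
        fs = contig.fragile_sites
        inside = fs[(fs > placement.start) & (fs < placement.end)]
        if placement.strand < 0:
            inside = placement.end - inside[::-1]
        else:
            inside = inside - placement.start
        for d in inside:
            if rng.random() < model.fragile_break_prob:
                length = float(d)
                break

    channels: list[np.ndarray] = []
    for ch in range(ref.n_channels):
        pos = contig.labels[ch]
        win = pos[(pos > placement.start) & (pos < placement.end)]
        if placement.strand > 0:
            local = win - placement.start
        else:
            local = (placement.end - win)[::-1]
        local = local[local < length]

        # label dropout
        if model.label_miss_rate > 0 and local.size:
            keep = rng.random(local.size) >= model.label_miss_rate
            local = local[keep]
        # sizing noise on inter-label intervals (leading interval included)
        if local.size and (model.sizing_sd0 > 0 or model.sizing_sd_scale > 0):
            gaps = np.diff(np.concatenate([[0.0], local]))
            sd = model.interval_sd(gaps)
            noisy = gaps + rng.normal(0.0, 1.0, gaps.size) * sd
            noisy = np.maximum(noisy, 1.0)
            local = np.cumsum(noisy)
        # spurious labels
        if model.false_label_rate > 0:
            n_false = rng.poisson(model.false_label_rate * length / 1e5)
            if n_false:
                local = np.sort(
                    np.concatenate([local, rng.uniform(0.0, length, n_false)])
                )
        local = local[(local > 0.5) & (local < length - 0.5)]
        # optical resolution: fuse labels closer than the limit
        if model.resolution_limit > 0 and local.size > 1:
            local = _fuse(local, model.resolution_limit)
        channels.append(np.sort(local))

    mol = Molecule(molecule_id, float(length), channels, origin=placement)

    if chimera_partner is not None:
        partner = observe_molecule(
            haplotypes, chimera_partner, model,
            seed=list(np.atleast_1d(seed)) + [1],
            molecule_id=molecule_id,
        )
        joined = [
            np.concatenate([a, b + mol.backbone_length])
            for a, b in zip(mol.labels, partner.labels)
        ]
        mol = Molecule(
            molecule_id,
            mol.backbone_length + partner.backbone_length,
            joined,
            origin=placement,
            chimera_of=chimera_partner,
        )
    return mol


def _fuse(pos: np.ndarray, limit: float) -> np.ndarray:
    """Greedy single-linkage fusion of labels closer than ``limit``."""
    out = []
    cluster = [pos[0]]
    for p in pos[1:]:
        if p - cluster[-1] < limit:
            cluster.append(p)
        else:
            out.append(float(np.mean(cluster)))
            cluster = [p]
    out.append(float(np.mean(cluster)))
    return np.array(out)


def simulate_run(
    haplotypes: ReferenceMap | Sequence[ReferenceMap],
    model: ErrorModel,
    coverage: float,
    seed: int,
    min_usable_labels: int = 8,
    length_params: dict | None = None,
) -> tuple[list[Molecule], RunSummary]:
    """Simulate a full run at the requested raw coverage.

    Deterministic under ``seed``.  ``map_rate`` in the returned summary is
    a simulation-time proxy (fraction of molecules carrying at least
    ``min_usable_labels`` labels); the pipeline recomputes the true
    molecule-to-reference map rate after alignment.
    """
    if isinstance(haplotypes, ReferenceMap):
        haplotypes = [haplotypes]
    length_params = length_params or {}
    placements = draw_molecule_lengths(
        coverage, haplotypes, seed=[seed, 0], **length_params
    )
    rng = np.random.default_rng([seed, 1])
    chimera_flags = rng.random(len(placements)) < model.chimera_rate
    molecules: list[Molecule] = []
    for k, pl in enumerate(placements):
        partner = None
        if chimera_flags[k]:
            other = draw_molecule_lengths(
                1e-12, haplotypes, seed=[seed, 3, k], **length_params
            )
            partner = other[0] if other else None
        molecules.append(
            observe_molecule(
                haplotypes, pl, model, seed=[seed, 10, k],
                molecule_id=k, chimera_partner=partner,
            )
        )
    total = float(sum(m.backbone_length for m in molecules))
    usable = sum(1 for m in molecules if m.n_labels >= min_usable_labels)
    map_rate = usable / len(molecules) if molecules else 0.0
    summary = RunSummary(
        total_bases=total,
        molecule_count=len(molecules),
        map_rate=map_rate,
        genome_size=haplotypes[0].total_length,
    )
    return molecules, summary


# ----------------------------------------------------------------- BNX I/O

_BNX_HEADER = "# omsv-bnx v1"


class BnxParseError(ValueError):
    pass


def write_bnx(path, molecules: Sequence[Molecule], truth_sidecar: bool = True) -> None:
    """Write molecules in the BNX dialect.

    Per molecule: a ``0`` header row (id, backbone length) and one row per
    channel with label positions.  Hidden origin truth goes to a
    comment-prefixed sidecar file ``<path>.truth`` that standard consumers
    can ignore.
    """
    with open(path, "w") as fh:
        fh.write(_BNX_HEADER + "\n")
        for mol in molecules:
            fh.write(f"0\t{mol.molecule_id}\t{mol.backbone_length:.1f}\n")
            for ch, pos in enumerate(mol.labels, start=1):
                cells = "\t".join(f"{p:.1f}" for p in pos)
                fh.write(f"{ch}" + ("\t" + cells if cells else "") + "\n")
    if truth_sidecar:
        with open(str(path) + ".truth", "w") as fh:
            for mol in molecules:
                rec = {
                    "id": mol.molecule_id,
                    "origin": asdict(mol.origin) if mol.origin else None,
                    "chimera_of": asdict(mol.chimera_of) if mol.chimera_of else None,
                }
                fh.write("# " + json.dumps(rec) + "\n")


def read_bnx(path) -> list[Molecule]:
    """Read the BNX dialect; loads the truth sidecar when present."""
    import os

    molecules: list[Molecule] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _BNX_HEADER:
            raise BnxParseError(f"line 1: expected {_BNX_HEADER!r}")
        current: Molecule | None = None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                tag = int(parts[0])
            except ValueError as exc:
                raise BnxParseError(f"line {lineno}: bad row tag") from exc
            if tag == 0:
                if len(parts) != 3:
                    raise BnxParseError(
                        f"line {lineno}: molecule header needs 3 columns"
                    )
                try:
                    current = Molecule(int(parts[1]), float(parts[2]), [])
                except ValueError as exc:
                    raise BnxParseError(f"line {lineno}: {exc}") from exc
                molecules.append(current)
            else:
                if current is None:
                    raise BnxParseError(f"line {lineno}: label row before header")
                try:
                    pos = np.array([float(x) for x in parts[1:]], dtype=float)
                except ValueError as exc:
                    raise BnxParseError(f"line {lineno}: bad position") from exc
                while len(current.labels) < tag:
                    current.labels.append(np.empty(0))
                current.labels[tag - 1] = pos
    truth_path = str(path) + ".truth"
    if os.path.exists(truth_path):
        truth: dict[int, dict] = {}
        with open(truth_path) as fh:
            for line in fh:
                line = line.strip()
                if not line.startswith("#"):
                    continue
                rec = json.loads(line[1:])
                truth[rec["id"]] = rec
        from omsv.molecule_sim import Placement as _P

        for mol in molecules:
            rec = truth.get(mol.molecule_id)
            if rec and rec["origin"]:
                mol.origin = _P(**rec["origin"])
            if rec and rec["chimera_of"]:
                mol.chimera_of = _P(**rec["chimera_of"])
    return molecules
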