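"""Synthetic cohort of X-linked dystrophinopathy families.

Generates desk-scale analogs of a clinical validation cohort: eleven
samples (eight affected males, three biological mothers) with structural
variants of exactly known size planted on region-restricted synthetic
X-chromosome references — six hemizygous multi-exon deletions (45,839 to
250,092 bp), one tandem duplication-insertion pair (12,968 bp in the
proband, 12,857 bp in the carrier mother), a heterozygous deletion
carrier, a confirmed non-carrier, and one 5.1-Mbp inversion sample mapped
with two enzyme channels.  Each scenario carries its exact planted truth
so pipeline output can be scored without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from omsv.reference_maps import (
    ReferenceMap,
    SVEdit,
    SVTruth,
    apply_sv_to_map,
    poisson_reference,
)
from omsv.sv_caller import SVCall

__all__ = [
    "CohortScenario",
    "ConcordanceReport",
    "COHORT_TABLE",
    "build_cohort",
    "score_concordance",
]

#: (sample_id, role, family, [(kind, size)], n_channels)
#: Mothers carry one edited and one wild-type haplotype; the non-carrier
#: mother carries two wild-type haplotypes.
COHORT_TABLE = [
    ("CDMD1003", "proband", "f1003", [("deletion", 182_665)], 1),
    ("CDMD1155", "proband", "f1155", [("deletion", 224_364)], 1),
    ("CDMD1156", "proband", "f1156", [("deletion", 59_771)], 1),
    ("CDMD1159", "proband", "f1159", [("deletion", 45_839)], 1),
    ("CDMD1131", "proband", "f1131", [("deletion", 250_092)], 1),
    ("CDMD1132", "mother", "f1131", [("deletion", 249_994)], 1),
    ("CDMD1157", "proband", "f1157", [("deletion", 184_882)], 1),
    ("CDMD1158", "mother", "f1157", [], 1),
    ("CDMD1163", "proband", "f1163", [("duplication", 12_968)], 1),
    ("CDMD1164", "mother", "f1163", [("duplication", 12_857)], 1),
    ("CDMD1187", "proband", "f1187", [("inversion", 5_100_000)], 2),
]

_CONTIG = "chrX"


@dataclass
class CohortScenario:
    """One simulated sample: references, haplotypes, truth, metadata."""

    sample_id: str
    role: str                      # proband (hemizygous X) or mother
    family: str
    reference: ReferenceMap        # unedited reference for SV calling
    haplotypes: list[ReferenceMap]
    truths: list[SVTruth]
    contig_ploidy: dict[str, int]
    coverage: float
    n_channels: int
    sim_seed: int

    @property
    def expected_zygosity(self) -> str:
        return "hemizygous" if self.role == "proband" else "heterozygous"


def _region_length(family: str) -> float:
    return 8_000_000.0 if family == "f1187" else 3_000_000.0


def build_cohort(
    seed: int = 0,
    spacing: float = 6000.0,
    coverage: float = 40.0,
) -> list[CohortScenario]:
    """Build all eleven cohort scenarios, seed-deterministically.

    Families share one reference region so mother/proband maps are
    comparable; SV positions are placed at seeded random locations with
    comfortable margins, and mother/proband events of one family share
    the same left breakpoint.
    """
    rng = np.random.default_rng([seed, 777])
    refs: dict[str, ReferenceMap] = {}
    starts: dict[str, float] = {}
    families = sorted({row[2] for row in COHORT_TABLE})
    for fam in families:
        length = _region_length(fam)
        n_ch = 2 if fam == "f1187" else 1
        refs[fam] = poisson_reference(
            length, spacing, n_ch, seed=[seed, 11, families.index(fam)],
            contig_id=_CONTIG)
        # largest event in the family bounds the placement margin
        big = max((size for sid, role, f, svs, nc in COHORT_TABLE
                   if f == fam for _, size in svs), default=0)
        margin = 0.15 * length
        starts[fam] = float(rng.uniform(margin,
                                        length - big - margin))
    scenarios = []
    for idx, (sid, role, fam, svs, n_ch) in enumerate(COHORT_TABLE):
        ref = refs[fam]
        edits = [SVEdit(kind, _CONTIG, starts[fam], starts[fam] + size)
                 for kind, size in svs]
        if edits:
            edited, truths = apply_sv_to_map(ref, edits)
        else:
            edited, truths = ref.copy(), []
        zyg = "hemizygous" if role == "proband" else "heterozygous"
        for t in truths:
            t.zygosity = zyg
        if role == "proband":
            haplotypes = [edited]
            ploidy = {_CONTIG: 1}
        else:
            haplotypes = [ref.copy(), edited]
            ploidy = {_CONTIG: 2}
        scenarios.append(CohortScenario(
            sample_id=sid, role=role, family=fam, reference=ref,
            haplotypes=haplotypes, truths=truths, contig_ploidy=ploidy,
            coverage=coverage, n_channels=n_ch,
            sim_seed=int(np.random.default_rng([seed, 23, idx])
                         .integers(2 ** 30)),
        ))
    return scenarios


# ------------------------------------------------------------- scoring

_TYPE_MATCH = {
    "deletion": {"deletion"},
    "duplication": {"insertion"},   # gain of material is called insertion
    "inversion": {"inversion"},
}


@dataclass
class SampleResult:
    sample_id: str
    matched: bool
    missing: list = field(default_factory=list)
    wrong: list = field(default_factory=list)
    extra_calls: int = 0
    breakpoint_errors: list = field(default_factory=list)


@dataclass
class ConcordanceReport:
    """Per-sample expected-vs-called comparison for a cohort."""

    results: list[SampleResult]

    @property
    def n_samples(self) -> int:
        return len(self.results)

    @property
    def n_concordant(self) -> int:
        return sum(1 for r in self.results if r.matched)

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_samples if self.results else 0.0

    def __str__(self) -> str:
        lines = [f"concordance {self.n_concordant}/{self.n_samples} "
                 f"({100 * self.concordance:.1f}%)"]
        for r in self.results:
            status = "ok" if r.matched else "DISCORDANT"
            extra = f" extra={r.extra_calls}" if r.extra_calls else ""
            miss = f" missing={r.missing}" if r.missing else ""
            wrong = f" wrong={r.wrong}" if r.wrong else ""
            lines.append(f"  {r.sample_id}: {status}{extra}{miss}{wrong}")
        return "\n".join(lines)


def _call_matches_truth(call: SVCall, truth: SVTruth, size_tol: float
                        ) -> bool:
    if call.type not in _TYPE_MATCH[truth.kind]:
        return False
    if truth.kind == "inversion":
        want = truth.size
        got = abs(call.size)
    else:
        want = truth.signed_size
        got = call.size
        if np.sign(got) != np.sign(want):
            return False
        want, got = abs(want), abs(got)
    if abs(got - want) > size_tol * want:
        return False
    if truth.zygosity != "unknown" and call.zygosity != truth.zygosity:
        return False
    return True


def score_concordance(
    scenarios: Sequence[CohortScenario],
    calls_by_sample: dict[str, Sequence[SVCall]],
    size_tol: float = 0.05,
) -> ConcordanceReport:
    """Score pipeline calls against the planted truth.

    A sample is concordant when every planted SV is called with the
    correct type, zygosity, and size within tolerance, and no extra
    calls are emitted; the non-carrier matches only with zero calls.
    A missing sample counts as discordant.
    """
    results = []
    for sc in scenarios:
        calls = list(calls_by_sample.get(sc.sample_id, []))
        if sc.sample_id not in calls_by_sample:
            results.append(SampleResult(sc.sample_id, False,
                                        missing=["sample"]))
            continue
        used: set[int] = set()
        missing, wrong = [], []
        bp_errors = []
        for truth in sc.truths:
            hit = None
            for j, call in enumerate(calls):
                if j in used:
                    continue
                if _call_matches_truth(call, truth, size_tol):
                    hit = j
                    break
            if hit is None:
                near = [c for c in calls
                        if c.type in _TYPE_MATCH[truth.kind]]
                (missing if not near else wrong).append(
                    f"{truth.kind}{truth.signed_size:+.0f}")
                continue
            used.add(hit)
            call = calls[hit]
            if truth.kind == "inversion":
                bp_errors.extend([
                    abs(call.left_breakpoint - truth.start),
                    abs(call.right_breakpoint - truth.end)])
            else:
                bp_errors.append(abs(call.left_breakpoint - truth.start))
                bp_errors.append(abs(call.right_breakpoint - truth.end)
                                 if truth.kind == "deletion" else
                                 abs(call.right_breakpoint - truth.start))
        extra = len(calls) - len(used)
        matched = not missing and not wrong and extra == 0
        results.append(SampleResult(sc.sample_id, matched, missing, wrong,
                                    extra, bp_errors))
    return ConcordanceReport(results)
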