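"""End-to-end driver: simulate -> assemble -> align -> call -> score.

Each enzyme channel is an independent run: its molecules are simulated,
assembled de novo, and its consensus maps are aligned to the reference
for SV calling; dual-channel samples combine the two call sets, which
narrows breakpoint-uncertainty intervals to the per-side intersections.
"""

from __future__ import annotations

import time

import numpy as np
from dataclasses import dataclass, field
from typing import Sequence

from omsv.assembler import ConsensusMap, StageLog, run_assembly
from omsv.config import PipelineConfig
from omsv.fixtures_cohort import (
    CohortScenario,
    ConcordanceReport,
    build_cohort,
    score_concordance,
)
from omsv.map_align import NullModel, fit_null
from omsv.molecule_sim import RunSummary, effective_coverage, simulate_run
from omsv.reference_maps import ReferenceMap
from omsv.sv_caller import (
    SVCall,
    call_structural_variants,
    combine_dual_enzyme,
    deduplicate_calls,
    refine_indel_sizes_from_molecules,
)

__all__ = ["SampleOutput", "run_sample", "run_cohort", "run_end_to_end"]


@dataclass
class SampleOutput:
    """Everything one simulated sample produced."""

    sample_id: str
    calls: list[SVCall]
    consensi_by_channel: dict[int, list[ConsensusMap]]
    stage_logs: dict[int, StageLog]
    run_summaries: dict[int, RunSummary]
    map_rates: dict[int, float]
    nulls: dict[int, NullModel] = field(default_factory=dict)
    elapsed_s: float = 0.0

    @property
    def effective_coverage_fold(self) -> float:
        """Effective coverage of channel 1 against its own region size."""
        s = self.run_summaries[1]
        rate = self.map_rates.get(1, s.map_rate)
        return effective_coverage(s.total_bases, s.genome_size, rate)


def run_sample(
    scenario: CohortScenario,
    config: PipelineConfig | None = None,
) -> SampleOutput:
    """Run the full pipeline on one cohort scenario."""
    config = config or PipelineConfig()
    t0 = time.time()
    calls_by_channel: dict[int, list[SVCall]] = {}
    consensi_by_channel: dict[int, list[ConsensusMap]] = {}
    logs: dict[int, StageLog] = {}
    summaries: dict[int, RunSummary] = {}
    map_rates: dict[int, float] = {}
    nulls: dict[int, NullModel] = {}
    for channel in range(1, scenario.n_channels + 1):
        molecules, summary = simulate_run(
            scenario.haplotypes, config.error_model, scenario.coverage,
            seed=scenario.sim_seed + channel)
        summaries[channel] = summary
        null = fit_null(scenario.reference, config.scoring,
                        n_draws=config.null_draws,
                        seed=scenario.sim_seed + 5000 + channel,
                        channel=channel)
        nulls[channel] = null
        from omsv.assembler import estimate_positions
        from omsv.sv_caller import fused_reference_channel
        fused = fused_reference_channel(scenario.reference, channel,
                                        config.scoring.resolution_limit)
        guide = np.concatenate([fused[c.contig_id]
                                for c in scenario.reference.contigs])
        hints = estimate_positions(molecules, np.ascontiguousarray(guide),
                                   config.assembly, channel=channel)
        consensi, log = run_assembly(molecules, config.assembly, null,
                                     channel=channel, position_hints=hints)
        consensi_by_channel[channel] = consensi
        logs[channel] = log
        calls, info = call_structural_variants(
            consensi, scenario.reference, config.scoring, null,
            rule=config.translocation, align_cutoff=config.align_cutoff,
            outlier_p=config.outlier_p,
            min_indel_size=config.min_indel_size,
            contig_ploidy=scenario.contig_ploidy, channel=channel)
        calls = refine_indel_sizes_from_molecules(
            calls, consensi, molecules, scenario.reference,
            config.scoring, channel=channel,
            contig_ploidy=scenario.contig_ploidy)
        calls = deduplicate_calls(calls)
        calls_by_channel[channel] = calls
        map_rates[channel] = info["map_rate"]
    if scenario.n_channels >= 2:
        calls = combine_dual_enzyme(calls_by_channel[1],
                                    calls_by_channel[2])
    else:
        calls = calls_by_channel[1]
    return SampleOutput(
        scenario.sample_id, calls, consensi_by_channel, logs, summaries,
        map_rates, nulls, elapsed_s=time.time() - t0)


def run_cohort(
    seed: int = 0,
    config: PipelineConfig | None = None,
    scenarios: Sequence[CohortScenario] | None = None,
    verbose: bool = False,
) -> tuple[dict[str, SampleOutput], ConcordanceReport,
           list[CohortScenario]]:
    """Simulate and analyze the whole cohort; score against truth."""
    config = config or PipelineConfig(seed=seed)
    if scenarios is None:
        scenarios = build_cohort(seed=seed, coverage=config.coverage)
    outputs: dict[str, SampleOutput] = {}
    for sc in scenarios:
        out = run_sample(sc, config)
        outputs[sc.sample_id] = out
        if verbose:
            print(f"{sc.sample_id}: {len(out.calls)} calls "
                  f"in {out.elapsed_s:.0f}s "
                  + "; ".join(f"{c.type}{c.size:+.0f}({c.zygosity})"
                              for c in out.calls))
    report = score_concordance(
        scenarios, {sid: o.calls for sid, o in outputs.items()})
    return outputs, report, list(scenarios)


def run_end_to_end(config: PipelineConfig,
                   verbose: bool = False
                   ) -> tuple[dict[str, SampleOutput], ConcordanceReport]:
    """Cohort driver used by the command-line interface."""
    outputs, report, _ = run_cohort(seed=config.seed, config=config,
                                    verbose=verbose)
    return outputs, report
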