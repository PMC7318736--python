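import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from csslkit.bin_map import infer_segments
from csslkit.synthetic import SimConfig, simulate_population


@pytest.fixture(scope="session")
def two_chrom_config() -> SimConfig:
    """A small two-chromosome population with realistic noise."""
    return SimConfig(
        chromosome_lengths={"A01": 20_000_000, "D01": 20_000_000},
        n_lines=50,
        segments_per_line=(1, 5),
        segment_length=(500_000, 5_000_000),
        het_fraction=0.1,
        snp_density=5.0,
        genotyping_error=0.01,
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(two_chrom_config):
    return simulate_population(two_chrom_config)


@pytest.fixture(scope="session")
def recovered_segments(two_chrom_config, small_population):
    snp_table, _, _ = small_population
    bins, segments = infer_segments(snp_table, two_chrom_config.genome)
    return bins, segments


def match_segments(truth_segments, recovered):
    """Pair each planted segment with its best-overlapping recovered segment
    of the same line/chromosome/state; returns (matches, misses, spurious)
    where matches are (truth, recovered) pairs."""
    matches, misses = [], []
    used = set()
    for ts in truth_segments:
        cands = [
            s
            for s in recovered
            if s.line == ts.line
            and s.chrom == ts.chrom
            and s.state == ts.state
            and min(s.end, ts.end) > max(s.start, ts.start)
        ]
        if not cands:
            misses.append(ts)
            continue
        best = max(cands, key=lambda s: min(s.end, ts.end) - max(s.start, ts.start))
        matches.append((ts, best))
        used.add(id(best))
    spurious = [
        s
        for s in recovered
        if not any(
            t.line == s.line and t.chrom == s.chrom and min(s.end, t.end) > max(s.start, t.start)
            for t in truth_segments
        )
    ]
    return matches, misses, spurious
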