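import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snapcall import pipeline, synthetic_data as sd

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: genome, annotation, tags, truth."""
    genome, genes, tags, truth = sd.simulate_benchmark(seed=BENCHMARK_SEED)
    tags_by = {f: g.reset_index(drop=True)
               for f, g in tags.groupby("source_factor")}
    return {"genome": genome, "genes": genes, "tags": tags,
            "tags_by_factor": tags_by, "truth": truth,
            "chrom_lengths": {c: len(s) for c, s in genome.items()}}


@pytest.fixture(scope="session")
def benchmark_result(benchmark):
    """Full pipeline run on the default benchmark."""
    return pipeline.run_pipeline(benchmark["tags_by_factor"],
                                 benchmark["genes"],
                                 benchmark["chrom_lengths"],
                                 genome=benchmark["genome"])


def random_tags(rng, n, chrom="chr1", L=10_000, tag_len=36,
                max_matches=1, max_times=1):
    """Seeded random tag DataFrame for property tests."""
    from snapcall.tag_model import make_tags

    start = rng.integers(0, L - tag_len, size=n)
    return make_tags(
        chrom=np.repeat(chrom, n), start=start, end=start + tag_len,
        strand=np.where(rng.random(n) < 0.5, "+", "-"),
        times_sequenced=rng.integers(1, max_times + 1, size=n),
        n_matches=rng.integers(1, max_matches + 1, size=n))
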