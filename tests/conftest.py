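import numpy as np
import pytest

from clonescape.genotypes import MultilocusGenotype, SampleRecord


def mlg(calls):
    return MultilocusGenotype(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genepop(tmp_path):
    """2 POP blocks x 3 samples x 2 loci, one missing call."""
    text = "\n".join(
        [
            "toy dataset",
            "LocusA",
            "LocusB",
            "POP",
            "north_1 , 100102 200200",
            "north_2 , 102102 200202",
            "north_3 , 100100 000000",
            "POP",
            "south_1 , 100102 200200",
            "south_2 , 104104 202202",
            "south_3 , 100104 200202",
        ]
    )
    path = tmp_path / "toy.gen"
    path.write_text(text + "\n")
    return path


def make_site(site, genotypes, copies=None):
    """SampleRecords for one site; ``copies`` replicates each genotype."""
    copies = copies or [1] * len(genotypes)
    records = []
    i = 0
    for g, k in zip(genotypes, copies):
        for _ in range(k):
            i += 1
            records.append(SampleRecord(f"{site}_{i}", site, f"Q{i % 3 + 1}", g))
    return records


def random_mlgs(rng, n, n_loci=3, n_alleles=6):
    """Distinct random genotypes (resampled until unique)."""
    out = []
    seen = set()
    while len(out) < n:
        calls = [
            tuple(sorted(rng.integers(100, 100 + 2 * n_alleles, 2)))
            for _ in range(n_loci)
        ]
        g = MultilocusGenotype(calls)
        if g.calls not in seen:
            seen.add(g.calls)
            out.append(g)
    return out


def hwe_mlgs(rng, n, freqs_per_locus, sizes_per_locus=None):
    """Genotypes drawn under Hardy-Weinberg at the given frequencies."""
    out = []
    for _ in range(n):
        calls = []
        for li, f in enumerate(freqs_per_locus):
            sizes = (
                sizes_per_locus[li]
                if sizes_per_locus is not None
                else 100 + 2 * np.arange(len(f))
            )
            a, b = rng.choice(len(f), size=2, p=f)
            calls.append((int(sizes[a]), int(sizes[b])))
        out.append(MultilocusGenotype(calls))
    return out
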