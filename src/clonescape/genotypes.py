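"""Multilocus genotypes, clone detection and clonality statistics.

Samples of a clonal plant collected within and across sites are scored at a
fixed panel of microsatellite loci. Samples sharing an identical multilocus
genotype (MLG) are treated as ramets of one genet (clone), and per-site
clonality is summarised by genotypic richness ``R = (G - 1) / (N - 1)`` where
``G`` is the number of distinct MLGs among ``N`` samples. The probability that
repeated observations of one MLG arose from independent sexual events rather
than clonal spread is assessed with P_gen / P_sex under Hardy-Weinberg
expectations. Per-site genetic diversity (mean allele number, observed and
Nei's unbiased expected heterozygosity) is computed from unique genets only,
since clonal replication otherwise biases allele frequencies.
"""

from __future__ import annotations

import itertools
import re
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "MultilocusGenotype",
    "SampleRecord",
    "ClonalPartition",
    "AlleleFrequencyTable",
    "DiversityStats",
    "read_genepop",
    "write_genepop",
    "read_genotypes_csv",
    "detect_clones",
    "genotypic_richness",
    "allele_frequencies",
    "pgen",
    "psex",
    "diversity_stats",
    "shared_mlgs",
]

#: sentinel for a fully missing locus call
MISSING = None


def _normalise_call(call):
    if call is None:
        return None
    a, b = call
    if a is None or b is None or a == 0 or b == 0:
        return None
    a, b = int(a), int(b)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class MultilocusGenotype:
    """Diploid allele calls over a fixed panel of loci.

    ``calls`` is a tuple with one entry per locus: either ``None`` (locus
    missing) or an ordered pair ``(a, b)`` with ``a <= b`` of integer allele
    sizes. Pair order at input is irrelevant: ``(b, a)`` is normalised to
    ``(a, b)``, so MLG equality is insensitive to allele ordering.
    """

    calls: tuple

    def __init__(self, calls: Iterable):
        object.__setattr__(
            self, "calls", tuple(_normalise_call(c) for c in calls)
        )

    @property
    def n_loci(self) -> int:
        return len(self.calls)

    @property
    def n_missing(self) -> int:
        return sum(c is None for c in self.calls)

    def is_heterozygous(self, locus: int):
        """True/False for a called locus, None when missing."""
        c = self.calls[locus]
        if c is None:
            return None
        return c[0] != c[1]

    def matches(self, other: "MultilocusGenotype", permissive: bool = False) -> bool:
        """Exact MLG equality; permissive mode lets missing loci match anything."""
        if len(self.calls) != len(other.calls):
            raise ValueError("locus counts differ")
        if not permissive:
            return self.calls == other.calls
        return all(
            a is None or b is None or a == b
            for a, b in zip(self.calls, other.calls)
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    site: str
    quadrat: str
    mlg: MultilocusGenotype


@dataclass
class ClonalPartition:
    """Partition of one site's samples into genets.

    ``genets`` maps each distinct MLG (represented by the first-encountered
    sample's genotype) to the list of member sample ids, in input order.
    """

    site: str
    genets: "OrderedDict[MultilocusGenotype, list[str]]"
    N: int = field(init=False)
    G: int = field(init=False)

    def __post_init__(self):
        self.N = sum(len(m) for m in self.genets.values())
        self.G = len(self.genets)
        if self.N == 0:
            raise ValueError(f"site {self.site!r}: empty partition")

    @property
    def R(self) -> float:
        return genotypic_richness(self.G, self.N)

    @property
    def largest_clone_fraction(self) -> float:
        return max(len(m) for m in self.genets.values()) / self.N

    def representative_mlgs(self) -> list[MultilocusGenotype]:
        return list(self.genets)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies over non-missing gene copies."""

    freqs: list  # list over loci of {allele: frequency}
    n_genes: list  # gene copies counted per locus

    def __post_init__(self):
        for i, f in enumerate(self.freqs):
            if f and abs(sum(f.values()) - 1.0) > 1e-9:
                raise ValueError(f"locus {i}: frequencies sum to {sum(f.values())}")

    @property
    def n_loci(self) -> int:
        return len(self.freqs)


@dataclass(frozen=True)
class DiversityStats:
    Na: float  # mean alleles per locus
    Ho: float  # observed heterozygosity (mean over loci)
    He: float  # Nei unbiased expected heterozygosity (mean over loci)


# ---------------------------------------------------------------------------
# GENEPOP I/O


def _parse_allele_string(tok: str, allele_digits: int, lineno: int):
    if len(tok) != 2 * allele_digits:
        raise ValueError(
            f"line {lineno}: allele string {tok!r} is not {2 * allele_digits} digits"
        )
    a = int(tok[:allele_digits])
    b = int(tok[allele_digits:])
    if a == 0 or b == 0:
        return None
    return (a, b)


def read_genepop(
    path,
    allele_digits: int = 3,
    site_names: Sequence[str] | None = None,
) -> list[SampleRecord]:
    """Read a GENEPOP file into sample records.

    The dialect is: a title line, one locus name per line (or a single
    comma-separated line), ``POP`` lines separating populations, and sample
    rows ``id , a1a2 a1a2 ...`` with ``allele_digits``-digit allele sizes and
    all-zero calls meaning missing. The site label of each POP block is the
    first sample's id unless ``site_names`` supplies one per block.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("not a GENEPOP file: fewer than 3 lines")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise ValueError("no locus names before first POP")
    records: list[SampleRecord] = []
    block = -1
    site = None
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            block += 1
            site = None
            continue
        if block < 0:
            raise ValueError(f"line {lineno}: sample row before any POP")
        if "," not in line:
            raise ValueError(f"line {lineno}: expected 'id , alleles...'")
        sid, rest = line.split(",", 1)
        sid = sid.strip()
        toks = rest.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"line {lineno}: {len(toks)} locus calls, expected {len(loci)}"
            )
        if site is None:
            site = site_names[block] if site_names is not None else sid
        calls = [_parse_allele_string(t, allele_digits, lineno) for t in toks]
        quadrat = _infer_quadrat(sid)
        records.append(SampleRecord(sid, site, quadrat, MultilocusGenotype(calls)))
    if not records:
        raise ValueError("no samples parsed")
    return records


_QUADRAT_RE = re.compile(r"[Qq](\d+)")


def _infer_quadrat(sample_id: str) -> str:
    m = _QUADRAT_RE.search(sample_id)
    return f"Q{m.group(1)}" if m else ""


def write_genepop(
    records: Sequence[SampleRecord],
    path,
    title: str = "clonescape export",
    locus_names: Sequence[str] | None = None,
    allele_digits: int = 3,
) -> None:
    """Write records as GENEPOP, one POP block per site (input site order)."""
    n_loci = records[0].mlg.n_loci
    if locus_names is None:
        locus_names = [f"Locus{i + 1}" for i in range(n_loci)]
    fmt = f"0{allele_digits}d"
    out = [title]
    out.extend(locus_names)
    by_site: "OrderedDict[str, list[SampleRecord]]" = OrderedDict()
    for r in records:
        by_site.setdefault(r.site, []).append(r)
    for site, rows in by_site.items():
        out.append("POP")
        for r in rows:
            toks = []
            for c in r.mlg.calls:
                if c is None:
                    toks.append("0" * (2 * allele_digits))
                else:
                    toks.append(f"{c[0]:{fmt}}{c[1]:{fmt}}")
            out.append(f"{r.sample_id} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def read_genotypes_csv(path) -> list[SampleRecord]:
    """Read long-format genotypes: sample,site,quadrat,locus,allele1,allele2."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    need = {"sample", "site", "quadrat", "locus", "allele1", "allele2"}
    if not need.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(need - set(df.columns))}")
    loci = list(dict.fromkeys(df["locus"]))
    records = []
    for (sid, site, quad), grp in df.groupby(
        ["sample", "site", "quadrat"], sort=False
    ):
        got = {row.locus: (row.allele1, row.allele2) for row in grp.itertuples()}
        calls = []
        for loc in loci:
            if loc not in got:
                raise ValueError(f"sample {sid}: locus {loc} absent")
            a, b = got[loc]
            calls.append(None if (a == 0 or b == 0) else (int(a), int(b)))
        records.append(SampleRecord(str(sid), str(site), str(quad), MultilocusGenotype(calls)))
    return records


# ---------------------------------------------------------------------------
# Clone detection and clonality statistics


def detect_clones(
    samples: Sequence[SampleRecord],
    missing_policy: str = "exact",
) -> "OrderedDict[str, ClonalPartition]":
    """Partition each site's samples into genets by MLG identity.

    ``missing_policy='exact'`` treats a missing locus as matching only another
    missing locus; ``'permissive'`` lets missing match any call (samples are
    greedily merged into the first compatible genet in input order, keeping
    the result deterministic). Representative genotype = first member's.
    """
    if missing_policy not in ("exact", "permissive"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if not samples:
        raise ValueError("no samples supplied")
    out: "OrderedDict[str, ClonalPartition]" = OrderedDict()
    by_site: "OrderedDict[str, list[SampleRecord]]" = OrderedDict()
    for s in samples:
        by_site.setdefault(s.site, []).append(s)
    for site, rows in by_site.items():
        genets: "OrderedDict[MultilocusGenotype, list[str]]" = OrderedDict()
        for r in rows:
            if missing_policy == "exact":
                bucket = genets.setdefault(r.mlg, [])
                bucket.append(r.sample_id)
            else:
                for rep in genets:
                    if rep.matches(r.mlg, permissive=True):
                        genets[rep].append(r.sample_id)
                        break
                else:
                    genets[r.mlg] = [r.sample_id]
        out[site] = ClonalPartition(site=site, genets=genets)
    return out


def genotypic_richness(G: int, N: int) -> float:
    """Genotypic richness R = (G - 1) / (N - 1); 0 = monoclonal, 1 = all unique."""
    if N < 2:
        raise ValueError("R undefined for N < 2")
    if not 1 <= G <= N:
        raise ValueError(f"need 1 <= G <= N, got G={G}, N={N}")
    return (G - 1) / (N - 1)


def allele_frequencies(
    mlgs: Sequence[MultilocusGenotype],
) -> AlleleFrequencyTable:
    """Allele frequencies per locus over non-missing gene copies."""
    if not mlgs:
        raise ValueError("no genotypes supplied")
    n_loci = mlgs[0].n_loci
    freqs, n_genes = [], []
    for loc in range(n_loci):
        counts: dict[int, int] = {}
        n = 0
        for g in mlgs:
            c = g.calls[loc]
            if c is None:
                continue
            counts[c[0]] = counts.get(c[0], 0) + 1
            counts[c[1]] = counts.get(c[1], 0) + 1
            n += 2
        freqs.append({a: k / n for a, k in sorted(counts.items())} if n else {})
        n_genes.append(n)
    return AlleleFrequencyTable(freqs=freqs, n_genes=n_genes)


def pgen(
    mlg: MultilocusGenotype,
    freqs: AlleleFrequencyTable,
    skip_missing: bool = False,
) -> float:
    """Probability of drawing ``mlg`` under Hardy-Weinberg at the given frequencies.

    Product over loci of ``p_a * p_b`` (times 2 for heterozygotes).
    """
    p = 1.0
    for loc, call in enumerate(mlg.calls):
        if call is None:
            if skip_missing:
                continue
            raise ValueError(f"locus {loc} missing; set skip_missing to ignore")
        table = freqs.freqs[loc]
        a, b = call
        if a not in table or b not in table:
            raise ValueError(f"locus {loc}: allele absent from frequency table")
        p *= table[a] * table[b] * (2.0 if a != b else 1.0)
    return p


def psex(p_gen: float, n_copies: int, N: int) -> float:
    """Probability of >= n_copies identical MLGs among N independent sexual events.

    Binomial tail ``sum_{i>=n_copies} C(N,i) p_gen^i (1-p_gen)^(N-i)``; small
    values mean the repeats are clones rather than sexual coincidences.
    """
    if n_copies < 2:
        raise ValueError("P_sex is defined for repeated genotypes (n_copies >= 2)")
    if not n_copies <= N:
        raise ValueError("n_copies must not exceed N")
    if not 0.0 <= p_gen <= 1.0:
        raise ValueError("p_gen must be in [0, 1]")
    return float(_sps.binom.sf(n_copies - 1, N, p_gen))


def diversity_stats(
    site_samples: Sequence[SampleRecord],
    unique_genets_only: bool = True,
) -> DiversityStats:
    """Mean alleles/locus, observed and Nei unbiased expected heterozygosity.

    With ``unique_genets_only`` (the default) ramet replicates are collapsed
    to one genet before counting, so clonal replication does not inflate
    allele frequencies. Unbiased He per locus is ``(2n/(2n-1)) (1 - sum p^2)``
    with ``n`` the genets called at that locus.
    """
    if not site_samples:
        raise ValueError("no samples supplied")
    mlgs = [s.mlg for s in site_samples]
    if unique_genets_only:
        seen: "OrderedDict[tuple, MultilocusGenotype]" = OrderedDict()
        for g in mlgs:
            seen.setdefault(g.calls, g)
        mlgs = list(seen.values())
    n_loci = mlgs[0].n_loci
    na, ho, he = [], [], []
    for loc in range(n_loci):
        called = [g.calls[loc] for g in mlgs if g.calls[loc] is not None]
        if not called:
            continue
        alleles = set(a for c in called for a in c)
        na.append(len(alleles))
        ho.append(sum(c[0] != c[1] for c in called) / len(called))
        n = len(called)
        counts: dict[int, int] = {}
        for c in called:
            counts[c[0]] = counts.get(c[0], 0) + 1
            counts[c[1]] = counts.get(c[1], 0) + 1
        p2 = sum((k / (2 * n)) ** 2 for k in counts.values())
        if n > 1:
            he.append((2 * n / (2 * n - 1)) * (1 - p2))
        else:
            he.append(0.0)
    return DiversityStats(
        Na=float(np.mean(na)), Ho=float(np.mean(ho)), He=float(np.mean(he))
    )


def shared_mlgs(
    partitions: Mapping[str, ClonalPartition],
) -> list[dict]:
    """MLGs observed at two or more sites, with a pooled-frequency P_sex.

    For each such MLG and each pair of sites sharing it, P_sex is computed
    from allele frequencies pooled over the pair's genets, with n_copies =
    ramets carrying the MLG in the pair and N = the pair's total samples.
    Returns a list of dicts: mlg, sites, and per-pair P_sex values.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two sites")
    occurrence: "OrderedDict[tuple, dict]" = OrderedDict()
    for site, part in partitions.items():
        for rep, members in part.genets.items():
            rec = occurrence.setdefault(rep.calls, {"mlg": rep, "sites": OrderedDict()})
            rec["sites"][site] = len(members)
    out = []
    for rec in occurrence.values():
        if len(rec["sites"]) < 2:
            continue
        pair_psex = {}
        for s1, s2 in itertools.combinations(rec["sites"], 2):
            pooled = allele_frequencies(
                partitions[s1].representative_mlgs()
                + partitions[s2].representative_mlgs()
            )
            pg = pgen(rec["mlg"], pooled, skip_missing=True)
            n_cop = rec["sites"][s1] + rec["sites"][s2]
            N = partitions[s1].N + partitions[s2].N
            pair_psex[(s1, s2)] = psex(pg, n_cop, N)
        out.append(
            {"mlg": rec["mlg"], "sites": list(rec["sites"]), "psex": pair_psex}
        )
    return out
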