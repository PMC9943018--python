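"""Per-family antisense enrichment and category frequency tables.

The null model is the pooled one-margin-fixed hypergeometric over all family
rows of the representative-genome contingency: with N classified riboswitches
of which K are antisense overall, a family of size n_f has antisense count
X ~ Hypergeometric(N, K, n_f), and the reported statistic is the inclusive
upper tail P(X >= k). The tail is evaluated in log space (log-factorial
based) so magnitudes down to the 1e-70 range survive; the family tables the
screen produces span 1e-62 to 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .gene_categories import CATEGORIES, CONSISTENT_CATEGORIES, CategoryAssignment
from .orientation import OrientationCall

_LOG10 = math.log(10.0)
_EARLY_STOP_NATS = 30 * _LOG10  # drop terms 30 orders below the running sum

# lazily-extended table of log(m!) so repeated small-N calls cost no lgamma
_LOGFACT: list[float] = [0.0, 0.0]


def _logfact(m: int) -> float:
    table = _LOGFACT
    while len(table) <= m:
        table.append(table[-1] + math.log(len(table)))
    return table[m]


def _log_binom(a: int, b: int) -> float:
    return _logfact(a) - _logfact(b) - _logfact(a - b)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Inclusive upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space from k upward with early termination once the terms
    have passed the mode and fallen 30 orders of magnitude below the running
    sum. ``hypergeom_sf(0, ...)`` is exactly 1.
    """
    for name, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if v != int(v):
            raise ValueError(f"{name} must be an integer")
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise ValueError(f"need 0 <= K <= N, 0 <= n <= N, k >= 0; "
                         f"got k={k}, N={N}, K={K}, n={n}")
    kmax = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    if k > kmax:
        return 0.0
    log_denom = _log_binom(N, n)
    mode = ((n + 1) * (K + 1)) // (N + 2)
    log_sum = -math.inf
    for j in range(k, kmax + 1):
        term = _log_binom(K, j) + _log_binom(N - K, n - j) - log_denom
        if log_sum == -math.inf:
            log_sum = term
        else:
            hi, lo = (log_sum, term) if log_sum >= term else (term, log_sum)
            log_sum = hi + math.log1p(math.exp(lo - hi))
        if j > mode and term < log_sum - _EARLY_STOP_NATS:
            break
    return min(1.0, math.exp(log_sum))


@dataclass(frozen=True)
class FamilyContingency:
    """Per-family sense/antisense counts with pooled margins."""

    rows: Mapping[str, tuple[int, int]]  # family -> (sense, antisense)

    def __post_init__(self) -> None:
        for fam, (s, a) in self.rows.items():
            if s < 0 or a < 0:
                raise ValueError(f"negative count for family {fam!r}")

    @property
    def N(self) -> int:
        return sum(s + a for s, a in self.rows.values())

    @property
    def K(self) -> int:
        return sum(a for _, a in self.rows.values())

    def n_f(self, family: str) -> int:
        s, a = self.rows[family]
        return s + a

    @classmethod
    def from_counts_stream(cls, stream: IO[str] | Iterable[str]) -> "FamilyContingency":
        """Read a bare counts TSV: family, sense, antisense."""
        rows: dict[str, tuple[int, int]] = {}
        for raw in stream:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            fam, s, a = line.split("\t")[:3]
            rows[fam] = (int(s), int(a))
        return cls(rows=rows)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    family: str
    sense: int
    antisense: int
    expected_antisense: float
    p_upper: float
    bh_adjusted: float | None = None


def build_contingency(calls: Iterable[OrientationCall]) -> FamilyContingency:
    """Tally sense/antisense counts per family; UNASSIGNED calls excluded."""
    rows: dict[str, list[int]] = {}
    for call in calls:
        if call.relation == "UNASSIGNED":
            continue
        row = rows.setdefault(call.family, [0, 0])
        row[1 if call.relation == "ANTISENSE_3P" else 0] += 1
    return FamilyContingency(rows={f: (s, a) for f, (s, a) in sorted(rows.items())})


def family_enrichment(ct: FamilyContingency,
                      bh_correction: bool = False) -> list[EnrichmentResult]:
    """One inclusive upper-tail hypergeometric result per family, sorted by
    ascending p-value. Raw p-values are primary; Benjamini-Hochberg is an
    optional extra column."""
    N, K = ct.N, ct.K
    results = []
    for family, (s, a) in ct.rows.items():
        n = s + a
        results.append(EnrichmentResult(
            family=family, sense=s, antisense=a,
            expected_antisense=(n * K / N) if N else 0.0,
            p_upper=hypergeom_sf(a, N, K, n) if N else 1.0))
    results.sort(key=lambda r: (r.p_upper, r.family))
    if bh_correction and results:
        from statsmodels.stats.multitest import multipletests
        adjusted = multipletests([r.p_upper for r in results],
                                 method="fdr_bh")[1]
        results = [EnrichmentResult(r.family, r.sense, r.antisense,
                                    r.expected_antisense, r.p_upper, float(q))
                   for r, q in zip(results, adjusted)]
    return results


@dataclass(frozen=True)
class CategoryTable:
    counts: Mapping[str, int]            # all ten categories, zero-filled
    relative: Mapping[str, float] = field(init=False, default=None)  # percent, 2 dp
    total: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        if any(v < 0 for v in counts.values()):
            raise ValueError("category counts must be >= 0")
        total = sum(counts.values())
        relative = {c: round(100.0 * v / total, 2) if total else 0.0
                    for c, v in counts.items()}
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "relative", relative)


def category_frequencies(assignments: Iterable[CategoryAssignment]) -> CategoryTable:
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    return CategoryTable(counts=counts)


def consistent_case_count(table: CategoryTable) -> int:
    """Number of regulated genes in the five biologically consistent groups
    (interconversion, cofactor, transporter, signaling, tf)."""
    return sum(table.counts[c] for c in CONSISTENT_CATEGORIES)


def write_enrichment_tsv(results: Iterable[EnrichmentResult], dest,
                         header_meta: Mapping[str, str] | None = None) -> None:
    with open(dest, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        has_bh = any(r.bh_adjusted is not None for r in results)
        cols = ["family", "sense", "antisense", "expected_antisense", "p_value"]
        if has_bh:
            cols.append("bh_adjusted")
        fh.write("\t".join(cols) + "\n")
        for r in results:
            row = [r.family, str(r.sense), str(r.antisense),
                   f"{r.expected_antisense:.2f}", f"{r.p_upper:.2E}"]
            if has_bh:
                row.append(f"{r.bh_adjusted:.2E}")
            fh.write("\t".join(row) + "\n")


def write_category_tsv(table: CategoryTable, dest,
                       header_meta: Mapping[str, str] | None = None) -> None:
    with open(dest, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("category\tcount\trelative_pct\n")
        for c in CATEGORIES:
            fh.write(f"{c}\t{table.counts[c]}\t{table.relative[c]:.2f}\n")
        fh.write(f"total\t{table.total}\t100.00\n")
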