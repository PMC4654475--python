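"""Cross-species repertoire comparison, overlap statistics, conservation classes.

Repertoires are rooted to reference gene names so a locus can be
followed across species.  Overlap of piC expression uses an RPM
threshold (10 RPM; 20 RPM in the stringent mode); overlap of mRNA
expression uses housekeeping-normalized RPKM ratios: two species share
a gene when |log10 x - log10 y| <= delta (0.5 default, 0.3 stringent)
and three species when the sample standard deviation of the three
log10 values <= sigma (0.3 default, 0.177 stringent).  Partition
differences are tested with a chi-square test over subset counts and
per-subset pooled two-proportion Z tests, Bonferroni-corrected.
Eutherian-Conserved (ECpiC) loci are those expressed above threshold
in at least k species of every clade (Primates, Glires,
Laurasiatherians by default); all others are Less-Conserved (LCpiC).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def build_repertoire_table(per_species: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Rows = reference-rooted locus names, columns = species, NaN = absent.

    ``per_species`` maps species -> {reference locus name -> RPM (or
    normalized RPKM)}.  Absent is distinct from 0: a locus missing from
    a species' dict is NaN, a locus measured at 0 is 0.
    """
    df = pd.DataFrame(per_species)
    df.index.name = "locus"
    if df.index.has_duplicates:
        raise ValueError("duplicate locus names in repertoire table")
    return df


@dataclass
class VennPartition:
    """Counts of loci per non-empty species subset, plus per-locus map."""

    species: tuple[str, ...]
    assignments: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def subset_counts(self) -> dict[frozenset[str], int]:
        counts: dict[frozenset[str], int] = {}
        for subset in self.assignments.values():
            counts[subset] = counts.get(subset, 0) + 1
        return counts

    @property
    def total(self) -> int:
        return len(self.assignments)

    def count(self, *species: str) -> int:
        return self.subset_counts.get(frozenset(species), 0)

    def all_subsets(self) -> list[frozenset[str]]:
        out = []
        for r in range(1, len(self.species) + 1):
            for combo in combinations(sorted(self.species), r):
                out.append(frozenset(combo))
        return out

    def counts_vector(self) -> np.ndarray:
        counts = self.subset_counts
        return np.array([counts.get(s, 0) for s in self.all_subsets()], dtype=float)


def pic_overlap(table: pd.DataFrame, min_rpm: float = 10.0) -> VennPartition:
    """Assign each locus to the subset of species where RPM >= min_rpm.

    Loci below threshold (or absent) everywhere are excluded.
    """
    species = tuple(table.columns)
    part = VennPartition(species)
    values = table.fillna(-math.inf)
    for locus, row in values.iterrows():
        subset = frozenset(sp for sp in species if row[sp] >= min_rpm)
        if subset:
            part.assignments[str(locus)] = subset
    return part


def expression_overlap(
    table: pd.DataFrame,
    pair_delta: float = 0.5,
    triple_sd: float = 0.3,
) -> VennPartition:
    """Overlap of expression profiles on the log10 similarity criteria.

    Supports 2 or 3 species.  Zero/negative/absent expression is
    treated as absent in that species (log10 undefined).  Assignment
    precedence is triple > pairwise > singleton; a locus meeting the
    pairwise criterion for more than one pair (but not the triple) is
    assigned to the pair with the smallest log10 difference, and a
    locus shared with no one falls to the singleton of the species
    where it is most expressed.
    """
    species = tuple(table.columns)
    if len(species) not in (2, 3):
        raise ValueError("expression_overlap supports 2 or 3 species")
    part = VennPartition(species)
    for locus, row in table.iterrows():
        present = {sp: row[sp] for sp in species
                   if pd.notna(row[sp]) and row[sp] > 0}
        if not present:
            continue
        logs = {sp: math.log10(v) for sp, v in present.items()}
        if len(species) == 3 and len(present) == 3:
            sd = float(np.std(list(logs.values()), ddof=1))
            if sd <= triple_sd:
                part.assignments[str(locus)] = frozenset(species)
                continue
        best_pair: frozenset[str] | None = None
        best_delta = math.inf
        for a, b in combinations(sorted(present), 2):
            delta = abs(logs[a] - logs[b])
            if delta <= pair_delta and delta < best_delta:
                best_pair, best_delta = frozenset((a, b)), delta
        if best_pair is not None:
            part.assignments[str(locus)] = best_pair
        else:
            top = max(present, key=lambda sp: (present[sp], sp))
            part.assignments[str(locus)] = frozenset((top,))
    return part


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z test; returns (z, two-sided p)."""
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, p


@dataclass
class PartitionComparison:
    chi2: float
    chi2_p: float
    subset_tests: pd.DataFrame  # per subset: z, p_raw, p_bonferroni, exact flag
    n_subsets_tested: int


def compare_partitions(venn_a: VennPartition, venn_b: VennPartition) -> PartitionComparison:
    """Test whether two Venn partitions over the same species differ.

    Chi-square over the subset-count vectors, plus a pooled
    two-proportion Z test per subset with Bonferroni correction
    (multiply by the number of subsets, cap at 1).  Subsets with
    expected counts < 1 are flagged and fall back to Fisher's exact
    test on the 2x2 table.
    """
    if set(venn_a.species) != set(venn_b.species):
        raise ValueError("partitions must cover the same species set")
    subsets = venn_a.all_subsets()
    ca = venn_a.subset_counts
    cb = venn_b.subset_counts
    va = np.array([ca.get(s, 0) for s in subsets], dtype=float)
    vb = np.array([cb.get(s, 0) for s in subsets], dtype=float)
    keep = (va + vb) > 0
    contingency = np.vstack([va[keep], vb[keep]])
    if np.array_equal(contingency[0], contingency[1]):
        chi2, chi2_p = 0.0, 1.0
    else:
        chi2, chi2_p, _, _ = stats.chi2_contingency(contingency, correction=False)
    na, nb = venn_a.total, venn_b.total
    tested = [s for s, k in zip(subsets, keep) if k]
    rows = []
    for s in tested:
        xa, xb = ca.get(s, 0), cb.get(s, 0)
        expected_min = min(
            (xa + xb) * na / (na + nb), (xa + xb) * nb / (na + nb)
        )
        exact = expected_min < 1
        if exact:
            warnings.warn(f"subset {sorted(s)}: expected count < 1, exact-test fallback")
            table = [[xa, na - xa], [xb, nb - xb]]
            _, p_raw = stats.fisher_exact(table)
            z = math.nan
        else:
            z, p_raw = two_proportion_z(xa, na, xb, nb)
        rows.append({
            "subset": "&".join(sorted(s)),
            "count_a": xa, "count_b": xb,
            "z": z, "p_raw": p_raw,
            "p_bonferroni": min(1.0, p_raw * len(tested)),
            "exact": exact,
        })
    return PartitionComparison(
        chi2=float(chi2), chi2_p=float(chi2_p),
        subset_tests=pd.DataFrame(rows), n_subsets_tested=len(tested),
    )


@dataclass
class ConservationCall:
    locus: str
    label: str                      # "ECpiC" or "LCpiC"
    evidence: dict[str, int]        # clade -> n species expressed


def classify_conservation(
    table: pd.DataFrame,
    clade_map: dict[str, str],
    min_rpm: float = 10.0,
    min_species_per_clade: int = 1,
) -> list[ConservationCall]:
    """ECpiC iff expressed (>= min_rpm) in >= k species of *every* clade."""
    clades: dict[str, list[str]] = {}
    for sp in table.columns:
        if sp not in clade_map:
            raise ValueError(f"species {sp} missing from clade map")
        clades.setdefault(clade_map[sp], []).append(sp)
    for clade, members in clades.items():
        if not members:
            raise ValueError(f"clade {clade} has no species")
    calls: list[ConservationCall] = []
    values = table.fillna(-math.inf)
    for locus, row in values.iterrows():
        evidence = {
            clade: int(sum(row[sp] >= min_rpm for sp in members))
            for clade, members in clades.items()
        }
        label = (
            "ECpiC"
            if all(n >= min_species_per_clade for n in evidence.values())
            else "LCpiC"
        )
        calls.append(ConservationCall(str(locus), label, evidence))
    return calls
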