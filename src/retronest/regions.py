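"""Region-preference statistics for nested insertions.

Each nested insertion is assigned to the region of its original element that
contains the insertion offset (half-open spans; a boundary base belongs to
the downstream region). Observed per-region counts are tested against
length-normalized expectations ``E_r = (L_r / L) * N`` computed per family
and summed, using a global chi-squared goodness-of-fit test followed by
per-region 1-df region-vs-rest chi-squares with Benjamini-Hochberg
correction. The module also builds the family x family autoinsertion matrix
and the 2x2 superfamily enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import AnnotatedElement, ElementModel, NestedPair

#: canonical display order for region labels (union of both superfamily schemas)
REGION_ORDER = (
    "LTR5", "pbs", "5UTR", "GAG", "GAG-AP", "AP",
    "AP-RT", "AP-INT", "RT", "INT-RT", "RT-RH", "RH", "RH-INT", "INT",
    "INT-CHR", "CHR", "CHR-ppt", "3UTR", "ppt", "LTR3",
)


def _region_sort_key(label: str) -> tuple[int, str]:
    # pooled labels look like "a+b"; sort by their first member
    first = label.split("+")[0]
    try:
        return (REGION_ORDER.index(first), label)
    except ValueError:
        return (len(REGION_ORDER), label)


def assign_region(pair: NestedPair, original: AnnotatedElement) -> str:
    """Label of the original's annotated sub-span containing the insertion.

    Falls back to the nearest region boundary (with a warning) if the offset
    lands in an annotation gap.
    """
    if not 0 <= pair.insertion_offset < original.length:
        raise ValueError(
            f"offset {pair.insertion_offset} outside original of length "
            f"{original.length}"
        )
    pos = original.start + pair.insertion_offset
    ordered = sorted(original.regions.items(), key=lambda kv: kv[1][0])
    for name, (s, e) in ordered:
        if s <= pos < e:
            pair.region_label = name
            return name
    # annotation gap: nearest boundary rule
    best_name, best_dist = None, None
    for name, (s, e) in ordered:
        dist = min(abs(pos - s), abs(pos - e))
        if best_dist is None or dist < best_dist:
            best_name, best_dist = name, dist
    warnings.warn(
        f"offset {pair.insertion_offset} of {pair.nested_id} falls in an "
        f"annotation gap of {original.id}; assigned nearest region {best_name}"
    )
    pair.region_label = best_name
    return best_name


@dataclass
class RegionSchema:
    """Mean region lengths per family for one superfamily."""

    superfamily: str
    region_order: list[str]
    family_lengths: dict[str, dict[str, float]]  # family -> region -> mean bp

    def element_mean_length(self, family: str) -> float:
        return float(sum(self.family_lengths[family].values()))


def schema_from_panel(panel: list[ElementModel], superfamily: str) -> RegionSchema:
    """Region schema from template mean lengths."""
    fams = {}
    names: list[str] = []
    for model in panel:
        if model.superfamily != superfamily:
            continue
        fams[model.family] = {name: float(mean) for name, mean, _ in model.layout}
        for name, _, _ in model.layout:
            if name not in names:
                names.append(name)
    names.sort(key=_region_sort_key)
    return RegionSchema(superfamily=superfamily, region_order=names,
                        family_lengths=fams)


def schema_from_elements(
    elements: list[AnnotatedElement], superfamily: str
) -> RegionSchema:
    """Region schema from the realized spans of annotated elements.

    For fragmented originals the genome-coordinate spans are expanded by
    their nested insertions, so per-region lengths are measured on the
    element's contiguous sequence where available (span lengths otherwise).
    """
    sums: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    names: list[str] = []
    for el in elements:
        if el.superfamily != superfamily or not el.regions:
            continue
        counts[el.family] = counts.get(el.family, 0) + 1
        fam = sums.setdefault(el.family, {})
        for name, (s, e) in el.regions.items():
            fam[name] = fam.get(name, 0.0) + (e - s)
            if name not in names:
                names.append(name)
    family_lengths = {
        f: {r: total / counts[f] for r, total in fam.items()}
        for f, fam in sums.items()
    }
    names.sort(key=_region_sort_key)
    return RegionSchema(superfamily=superfamily, region_order=names,
                        family_lengths=family_lengths)


def expected_counts(family_lengths: dict[str, float], n_nested: int) -> dict[str, float]:
    """``E_r = (L_r / L) * N`` for one family; sums exactly to N."""
    if n_nested < 0:
        raise ValueError("nested count must be >= 0")
    total = sum(family_lengths.values())
    if total <= 0:
        raise ValueError("invalid schema: zero total length")
    return {r: n_nested * length / total for r, length in family_lengths.items()}


@dataclass
class RegionPreferenceTable:
    """Observed-vs-expected region counts plus the test results."""

    table: pd.DataFrame  # index region; columns observed, expected, p_raw, p_adj, significant
    chi2: float
    df: int
    p_global: float
    pooled: dict[str, list[str]] = field(default_factory=dict)


def _pool_sparse(order: list[str], O: dict[str, float],
                 E: dict[str, float]) -> tuple[list[str], dict, dict, dict]:
    """Pool regions with E < 1 into their adjacent smaller neighbour."""
    order = [r for r in order if r in E]
    members = {r: [r] for r in order}
    O = dict(O)
    E = dict(E)
    while len(order) > 1:
        sparse = [r for r in order if E[r] < 1.0]
        if not sparse:
            break
        r = min(sparse, key=lambda x: E[x])
        i = order.index(r)
        neighbours = [order[j] for j in (i - 1, i + 1) if 0 <= j < len(order)]
        target = min(neighbours, key=lambda x: E[x])
        E[target] += E.pop(r)
        O[target] = O.get(target, 0) + O.pop(r, 0)
        members[target] = members[target] + members.pop(r)
        order.remove(r)
    pooled = {f"{'+'.join(m)}": m for r, m in members.items() if len(m) > 1}
    relabel = {r: "+".join(members[r]) for r in order}
    order = [relabel[r] for r in order]
    O = {relabel.get(r, r): v for r, v in O.items()}
    E = {relabel.get(r, r): v for r, v in E.items()}
    return order, O, E, pooled


def gof_test(
    observed: dict[str, float],
    expected: dict[str, float],
    region_order: list[str] | None = None,
    alpha: float = 0.05,
) -> RegionPreferenceTable:
    """Global chi-squared GOF plus per-region follow-up with BH correction.

    The global statistic is ``X^2 = sum (O_r - E_r)^2 / E_r`` with
    ``df = #regions - 1`` (expectations rescaled to the observed total, as a
    GOF test requires). Each region is then tested region-vs-rest on a 1-df
    chi-square, and the per-region p-values are Benjamini-Hochberg adjusted.
    Regions with E < 1 are pooled with their adjacent smaller neighbour
    before testing.
    """
    if set(observed) - set(expected):
        raise ValueError(
            f"regions {sorted(set(observed) - set(expected))} have no expectation"
        )
    order = region_order or sorted(expected, key=_region_sort_key)
    total_obs = float(sum(observed.values()))
    if total_obs <= 0:
        raise ValueError("no observations")
    total_exp = float(sum(expected.values()))
    scaled = {r: e * total_obs / total_exp for r, e in expected.items()}
    order, O, E, pooled = _pool_sparse(list(order), dict(observed), scaled)

    obs = np.array([O.get(r, 0.0) for r in order], dtype=float)
    exp = np.array([E[r] for r in order], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(order) - 1
    p_global = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    p_raw = []
    for o, e in zip(obs, exp):
        stat = (o - e) ** 2 / e + ((total_obs - o) - (total_obs - e)) ** 2 / (total_obs - e) \
            if total_obs - e > 0 else np.inf
        p_raw.append(float(stats.chi2.sf(stat, 1)))
    if len(p_raw) > 1:
        _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    else:
        p_adj = np.asarray(p_raw)

    table = pd.DataFrame(
        {
            "observed": obs,
            "expected": exp,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=pd.Index(order, name="region"),
    )
    return RegionPreferenceTable(table=table, chi2=chi2, df=df,
                                 p_global=p_global, pooled=pooled)


def region_preference_table(
    pairs: list[NestedPair],
    elements_by_id: dict[str, AnnotatedElement],
    schema: RegionSchema,
    alpha: float = 0.05,
) -> RegionPreferenceTable | None:
    """Observed vs expected region counts for one superfamily's originals.

    Pairs whose original is not in the schema's superfamily are skipped.
    Expectations are computed per original family and summed, mirroring the
    length-normalization by family mean region lengths.
    """
    observed: dict[str, float] = {}
    n_by_family: dict[str, int] = {}
    for pair in pairs:
        original = elements_by_id.get(pair.original_id)
        if original is None or original.superfamily != schema.superfamily:
            continue
        if original.family not in schema.family_lengths:
            continue
        label = pair.region_label or assign_region(pair, original)
        observed[label] = observed.get(label, 0) + 1
        n_by_family[original.family] = n_by_family.get(original.family, 0) + 1
    if not observed:
        return None
    expected: dict[str, float] = {}
    for family, n in n_by_family.items():
        for r, e in expected_counts(schema.family_lengths[family], n).items():
            expected[r] = expected.get(r, 0.0) + e
    return gof_test(observed, expected, region_order=schema.region_order,
                    alpha=alpha)


def autoinsertion_matrix(
    pairs: list[NestedPair],
) -> tuple[pd.DataFrame, pd.Series]:
    """family x family insertion count matrix and per-family autoinsertion
    fraction (diagonal over row sum; rows = nested family)."""
    rows = [(p.nested_family, p.original_family) for p in pairs]
    if not rows:
        return pd.DataFrame(), pd.Series(dtype=float)
    df = pd.DataFrame(rows, columns=["nested", "original"])
    matrix = pd.crosstab(df["nested"], df["original"])
    families = sorted(set(matrix.index) | set(matrix.columns))
    matrix = matrix.reindex(index=families, columns=families, fill_value=0)
    diag = pd.Series(np.diag(matrix), index=families, dtype=float)
    row_sums = matrix.sum(axis=1).astype(float)
    fractions = (diag / row_sums.replace(0, np.nan)).fillna(0.0)
    return matrix, fractions


def superfamily_enrichment(
    nested_by_sf: tuple[int, int],
    nonnested_by_sf: tuple[int, int],
    continuity_correction: bool = False,
) -> dict[str, float]:
    """Pearson chi-square test of independence on the 2x2 table
    (rows nested/non-nested, columns gypsy/copia)."""
    table = np.array([nested_by_sf, nonnested_by_sf], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def recent_old_split(
    pairs: list[NestedPair],
    recent_max: float = 1.0,
    old_min: float = 5.0,
) -> tuple[list[NestedPair], list[NestedPair]]:
    """Split pairs by LTR identity delta into recent (0 < delta <= 1 point)
    and old (delta >= 5 points) disjoint subsets; intermediate pairs and
    pairs without a delta are excluded."""
    recent = [p for p in pairs
              if p.identity_delta is not None and 0.0 < p.identity_delta <= recent_max]
    old = [p for p in pairs
           if p.identity_delta is not None and p.identity_delta >= old_min]
    return recent, old
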