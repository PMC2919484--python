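"""Synthetic-lethality benchmark construction and ROC / precision-recall scoring.

Positives are experimentally reported synthetic lethal (SL) or synthetic
growth defect (SGD) gene pairs with both genes in the network.  Negatives
are pairs presumed tested but not reported interacting: each gene has at
least one SL/SGD interaction anywhere in the table, and at least one of the
two has >= 5 such interactions as the query of a high-throughput screen.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .local import PairScoreTable
from .network import StoichiometricModel

SL_TYPES = ("synthetic_lethality", "synthetic_growth_defect")

_BIOGRID_TYPE_MAP = {
    "synthetic lethality": "synthetic_lethality",
    "synthetic growth defect": "synthetic_growth_defect",
}


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class InteractionTable:
    """Genetic-interaction records with screen metadata.

    ``records`` columns: gene_a, gene_b, interaction_type, is_high_throughput,
    query_gene (the screen query of the pair, when known, else "").
    """

    records: pd.DataFrame

    REQUIRED = ("gene_a", "gene_b", "interaction_type")
    METADATA = ("is_high_throughput", "query_gene")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"interaction table lacks columns: {missing}")
        df = self.records.copy()
        df = df[df.gene_a != df.gene_b]  # no self-interactions
        swapped = df.gene_a > df.gene_b
        df.loc[swapped, ["gene_a", "gene_b"]] = df.loc[swapped, ["gene_b", "gene_a"]].values
        self.records = df.reset_index(drop=True)

    @property
    def has_screen_metadata(self) -> bool:
        return all(c in self.records.columns for c in self.METADATA)

    @classmethod
    def from_biogrid(cls, path: str) -> "InteractionTable":
        """Read BioGRID tab2 (or tab) format.

        The experimental-system column maps to the interaction type; the
        throughput column (tab2) sets ``is_high_throughput``; interactor A
        is recorded as the query gene, following the BioGRID convention for
        genetic screens.
        """
        df = pd.read_csv(path, sep="\t", comment=None, dtype=str, low_memory=False)
        cols = {c.lower().replace(" ", "_"): c for c in df.columns}

        def pick(*names):
            for nm in names:
                if nm in cols:
                    return cols[nm]
            return None

        a = pick("official_symbol_interactor_a", "systematic_name_interactor_a",
                 "officialsymbola", "interactor_a")
        b = pick("official_symbol_interactor_b", "systematic_name_interactor_b",
                 "officialsymbolb", "interactor_b")
        sys_col = pick("experimental_system", "experimental_system_name")
        if a is None or b is None or sys_col is None:
            raise ValueError("unrecognized BioGRID format: interactor/system "
                             "columns not found")
        out = pd.DataFrame({
            "gene_a": df[a].str.strip(),
            "gene_b": df[b].str.strip(),
            "interaction_type": df[sys_col].str.strip().str.lower()
                                  .map(_BIOGRID_TYPE_MAP).fillna("other"),
        })
        thr = pick("throughput")
        if thr is not None:
            out["is_high_throughput"] = df[thr].str.contains("High", case=False, na=False)
            out["query_gene"] = df[a].str.strip()
        return cls(out)


@dataclass
class InteractionBenchmark:
    """Labelled positive/negative pair sets over a gene universe."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        for pair in itertools.chain(self.positives, self.negatives):
            if not set(pair) <= self.universe:
                raise ValueError(f"pair {pair} outside universe")


def define_positives(table: InteractionTable, universe: set[str]) -> set[tuple[str, str]]:
    """SL/SGD pairs with both genes in the universe, deduplicated."""
    if not universe:
        raise ValueError("universe is empty")
    df = table.records
    df = df[df.interaction_type.isin(SL_TYPES)]
    pairs = {_norm_pair(a, b) for a, b in zip(df.gene_a, df.gene_b)
             if a in universe and b in universe}
    return pairs


def define_negatives(table: InteractionTable, universe: set[str]) -> set[tuple[str, str]]:
    """Presumed-tested non-interacting pairs.

    A pair qualifies when each gene has >= 1 SL/SGD interaction in the table,
    one of the two has >= 5 SL/SGD interactions as a high-throughput query,
    and the pair is not a positive.
    """
    if not table.has_screen_metadata:
        raise ValueError(
            "interaction table lacks is_high_throughput/query_gene metadata; "
            "regenerate it with the synthetic generator's schema or use "
            "BioGRID tab2 input")
    df = table.records[table.records.interaction_type.isin(SL_TYPES)]
    n_sl = Counter(df.gene_a) + Counter(df.gene_b)
    ht = df[df.is_high_throughput.astype(bool)]
    n_query = Counter(ht.query_gene)
    positives = define_positives(table, universe)

    tested = sorted(g for g in universe if n_sl[g] >= 1)
    heavy = {g for g in tested if n_query[g] >= 5}
    out = set()
    for a, b in itertools.combinations(tested, 2):
        if (a in heavy or b in heavy) and (a, b) not in positives:
            out.add((a, b))
    return out


def build_benchmark(table: InteractionTable, universe: set[str]) -> InteractionBenchmark:
    return InteractionBenchmark(define_positives(table, universe),
                                define_negatives(table, universe), set(universe))


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass
class CurvePoints:
    """ROC and precision-recall curves with their summary statistics."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    auc: float
    max_f: float
    n_pos: int
    n_neg: int
    method: str = ""

    def summary(self) -> dict:
        return {"method": self.method, "AUC": self.auc, "F": self.max_f,
                "n_pos": self.n_pos, "n_neg": self.n_neg}

    def write(self, curve_path: str, summary_path: str | None = None,
              downsample: int | None = None) -> None:
        roc = pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})
        pr = pd.DataFrame({"recall": self.recall, "precision": self.precision})
        if downsample:
            roc = _thin(roc, downsample)
            pr = _thin(pr, downsample)
        roc["curve"] = "roc"
        pr["curve"] = "pr"
        pd.concat([roc, pr]).to_csv(curve_path, sep="\t", index=False)
        if summary_path:
            with open(summary_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def _thin(df: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep ~k evenly spaced curve points (display only; stats unchanged)."""
    if len(df) <= k:
        return df
    idx = np.unique(np.linspace(0, len(df) - 1, k).round().astype(int))
    return df.iloc[idx]


def evaluate(scores: PairScoreTable, bench: InteractionBenchmark,
             method: str | None = None) -> CurvePoints:
    """Threshold sweep over distinct score values; AUC by trapezoid, max F.

    Tied scores share a threshold bucket, matching the stepping convention
    of standard ROC tooling.
    """
    if not bench.positives or not bench.negatives:
        raise ValueError("benchmark needs at least one positive and one negative")
    idx = {e: i for i, e in enumerate(scores.enzymes)}
    pairs = sorted(bench.positives) + sorted(bench.negatives)
    missing = [p for p in pairs if p[0] not in idx or p[1] not in idx]
    if missing:
        raise ValueError(f"{len(missing)} benchmark pairs missing from the "
                         f"score table, e.g. {missing[0]}")
    y = np.r_[np.ones(len(bench.positives)), np.zeros(len(bench.negatives))]
    s = np.array([scores.values[idx[a], idx[b]] for a, b in pairs])
    fpr, tpr, roc_thr = skmetrics.roc_curve(y, s, drop_intermediate=False)
    prec, rec, pr_thr = skmetrics.precision_recall_curve(y, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 2 * prec * rec / (prec + rec)
    return CurvePoints(fpr, tpr, roc_thr, prec, rec, pr_thr,
                       auc=float(skmetrics.auc(fpr, tpr)),
                       max_f=float(np.nanmax(f)),
                       n_pos=len(bench.positives), n_neg=len(bench.negatives),
                       method=method or scores.method)


# ---------------------------------------------------------------------------
# Compartment sharing vs synthetic lethality
# ---------------------------------------------------------------------------

def contingency_test(counts: np.ndarray, test: str = "fisher") -> dict:
    """Two-sided association test and rate ratio for a 2x2 table.

    Rows: shares-a-compartment yes/no; columns: SL yes/no.  Returns the
    odds ratio, the ratio of SL rates between rows, and the p-value
    (Fisher exact by default, continuity-corrected chi-square otherwise).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if test == "fisher":
        odds, p = stats.fisher_exact(counts, alternative="two-sided")
    elif test == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=True)
        a, b = counts[0]
        c, d = counts[1]
        odds = (a * d) / (b * c) if b * c else np.inf
    else:
        raise ValueError("test must be 'fisher' or 'chi2'")
    rate_share = counts[0, 0] / counts[0].sum()
    rate_noshare = counts[1, 0] / counts[1].sum()
    return {"odds_ratio": float(odds), "p_value": float(p),
            "rate_ratio": float(rate_share / rate_noshare) if rate_noshare else np.inf,
            "counts": counts.astype(int).tolist()}


def gene_compartments(model: StoichiometricModel) -> dict[str, set[str]]:
    """Gene -> union of compartments of the metabolites of its reactions."""
    part = model.participation_matrix()
    comp_of = np.array([model.compartment_of.get(m, "") for m in model.metabolite_ids],
                       dtype=object)
    out: dict[str, set[str]] = {}
    for gi, gene in enumerate(model.gene_ids):
        rxns = np.flatnonzero(model.E[:, gi])
        mets = np.flatnonzero(part[:, rxns].sum(axis=1) > 0)
        out[gene] = {c for c in comp_of[mets] if c}
    return out


def compartment_sl_table(model: StoichiometricModel, bench: InteractionBenchmark,
                         test: str = "fisher") -> dict:
    """Cross-tabulate SL status x shares-a-compartment over all universe pairs.

    SL pairs are the benchmark positives; all other universe pairs count as
    non-SL, mirroring the tabulation of genome-wide SL sharing rates.
    """
    comp = gene_compartments(model)
    genes = sorted(bench.universe)
    counts = np.zeros((2, 2))
    for a, b in itertools.combinations(genes, 2):
        share = bool(comp.get(a, set()) & comp.get(b, set()))
        sl = (a, b) in bench.positives or (b, a) in bench.positives
        counts[0 if share else 1, 0 if sl else 1] += 1
    return contingency_test(counts, test=test)
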