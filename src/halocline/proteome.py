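"""Salt-in functional signatures from predicted metaproteomes.

Per-protein isoelectric points are computed from a Henderson-
Hasselbalch net-charge model (side chains D, E, C, Y acidic; H, K, R
basic; plus the two termini) solved by bisection, and summarized as a
community-weighted mean pI — salt-in strategist assemblages shift this
signature acidic.  Potassium transport potential sums the relative
abundance of features annotated with the Trk system KOs (trkH K03498,
trkA K03499).  Osmoadaptation strategies (compatible-solute uptake,
glycerol utilization, trehalose/ectoine biosynthesis, ...) are profiled
as presence/absence of catalog genes per MAG with a per-strategy
completeness flag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import AbundanceTable, ProteinRecord

logger = logging.getLogger(__name__)

ACIDIC = ("D", "E", "C", "Y")
BASIC = ("H", "K", "R")
#: residues treated as charge-neutral (ambiguity codes and rare residues)
NEUTRAL_AMBIGUOUS = set("BZXUO")

TRK_KOS = ("K03498", "K03499")  # trkH, trkA


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa constants (EMBOSS values by default)."""

    D: float = 3.9
    E: float = 4.1
    C: float = 8.5
    Y: float = 10.1
    H: float = 6.5
    K: float = 10.8
    R: float = 12.5
    n_terminus: float = 8.6
    c_terminus: float = 3.6

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


EMBOSS_PKA = PkaSet()
PKA_SETS = {"emboss": EMBOSS_PKA}


def _residue_counts(sequence: str) -> dict[str, int]:
    seq = sequence.upper()
    counts = {aa: seq.count(aa) for aa in ACIDIC + BASIC}
    unknown = set(seq) - set("ACDEFGHIKLMNPQRSTVWY")
    odd = unknown - NEUTRAL_AMBIGUOUS
    if odd:
        logger.warning("unrecognized residues treated as neutral: %s", sorted(odd))
    return counts


def _charge_from_counts(
    counts: Mapping[str, int], ph: float | np.ndarray, pka: PkaSet
) -> float | np.ndarray:
    ph = np.asarray(ph, dtype=float)
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka.n_terminus))
    for aa in BASIC:
        pos = pos + counts[aa] / (1.0 + 10.0 ** (ph - getattr(pka, aa)))
    neg = 1.0 / (1.0 + 10.0 ** (pka.c_terminus - ph))
    for aa in ACIDIC:
        neg = neg + counts[aa] / (1.0 + 10.0 ** (getattr(pka, aa) - ph))
    out = pos - neg
    return float(out) if out.ndim == 0 else out


def net_charge(sequence: str, ph: float, pka: PkaSet = EMBOSS_PKA) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch model).

    Includes the free N- and C-termini; ambiguous residues (B, Z, X, U,
    O) contribute no charge.
    """
    if len(sequence) == 0:
        raise ValueError("cannot compute the charge of an empty sequence")
    return _charge_from_counts(_residue_counts(sequence), ph, pka)


def predict_pi(sequence: str, pka: PkaSet = EMBOSS_PKA, tol: float = 1e-4) -> float:
    """Isoelectric point: the pH of zero net charge, found by bisection.

    The charge is strictly decreasing in pH and both termini guarantee a
    sign change on [0, 14], so bisection always converges.  Iteration
    stops when |charge| < tol or the bracket is narrower than 1e-6 pH.
    """
    if len(sequence) == 0:
        raise ValueError("cannot compute the pI of an empty sequence")
    counts = _residue_counts(sequence)
    lo, hi = 0.0, 14.0
    mid = 7.0
    # drive the bracket below 1e-6 pH so the result is accurate in pH
    # units even where the charge curve is nearly flat
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if _charge_from_counts(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return mid


def weighted_mean_pi(
    proteins: Sequence[ProteinRecord],
    pka: PkaSet = EMBOSS_PKA,
    equal_weights: bool = False,
) -> float:
    """Abundance-weighted mean isoelectric point of a proteome.

    Weights default to each protein's contig relative abundance; with
    ``equal_weights`` the plain arithmetic mean is returned.
    """
    if not proteins:
        raise ValueError("empty proteome")
    w = np.ones(len(proteins)) if equal_weights else np.array(
        [p.weight for p in proteins], dtype=float
    )
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    pis = np.array([predict_pi(p.sequence, pka) for p in proteins])
    return float(np.average(pis, weights=w))


def pi_table(
    proteins: Sequence[ProteinRecord], pka: PkaSet = EMBOSS_PKA
) -> pd.DataFrame:
    """Per-protein pI table (id, contig, length, weight, pi)."""
    return pd.DataFrame(
        {
            "id": [p.id for p in proteins],
            "contig": [p.contig for p in proteins],
            "length": [len(p.sequence) for p in proteins],
            "weight": [p.weight for p in proteins],
            "pi": [predict_pi(p.sequence, pka) for p in proteins],
        }
    )


def trk_potential(
    annotations: Mapping[str, Iterable[str]],
    table: AbundanceTable,
    kos: Sequence[str] = TRK_KOS,
) -> pd.Series:
    """Per-sample % abundance of features carrying any Trk-system KO.

    A feature carrying several of the KOs is counted once (set union
    over features, not over annotations).
    """
    kos = set(kos)
    carriers = [
        f for f in table.features if kos & set(annotations.get(f, ()))
    ]
    out = table.values.loc[carriers].sum(axis=0)
    out.name = "trk_potential_pct"
    return out


# --------------------------------------------------------------------------
# osmoadaptation gene catalog

_GENE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_\-]*$")
_KO_RE = re.compile(r"^K\d{5}$")


@dataclass
class OsmoGeneCatalog:
    """Named osmoadaptation strategies mapped to gene symbols and KO aliases."""

    strategies: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen_ko: dict[str, str] = {}
        for strat, genes in self.strategies.items():
            if not genes:
                raise ValueError(f"strategy {strat!r} has no genes")
            for gene, kos in genes.items():
                if not _GENE_RE.match(gene):
                    raise ValueError(f"unknown gene symbol {gene!r} in strategy {strat!r}")
                for ko in kos:
                    if not _KO_RE.match(ko):
                        raise ValueError(f"malformed KO {ko!r} for gene {gene!r}")
                    if ko in seen_ko and seen_ko[ko] != strat:
                        raise ValueError(
                            f"KO {ko} appears in both {seen_ko[ko]!r} and {strat!r}"
                        )
                    seen_ko[ko] = strat

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.strategies.values() for g in genes]

    def aliases(self, gene: str) -> set[str]:
        """Tokens (lower-cased symbol + KOs) that count as hits for a gene."""
        for genes in self.strategies.values():
            if gene in genes:
                return {gene.lower(), *genes[gene]}
        raise KeyError(gene)


def load_osmo_catalog(path: str | None = None) -> OsmoGeneCatalog:
    """Load the osmoadaptation catalog (the shipped YAML by default)."""
    if path is None:
        text = (
            resources.files("halocline").joinpath("data/osmo_genes.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("osmo catalog must map strategies to gene tables")
    strategies = {
        str(strat): {str(g): [str(k) for k in kos] for g, kos in genes.items()}
        for strat, genes in raw.items()
    }
    return OsmoGeneCatalog(strategies=strategies)


def osmo_gene_profile(
    mag_annotations: Mapping[str, Iterable[str]],
    catalog: OsmoGeneCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence of catalog genes per MAG, plus strategy completeness.

    Annotation tokens may be gene symbols (case-insensitive) or KO
    identifiers.  A strategy is "complete" for a MAG when every gene of
    the strategy is present (e.g. glycerol utilization requires glpK
    together with the full GlpA/GlpB/GlpC dehydrogenase).
    """
    cat = catalog or load_osmo_catalog()
    mags = list(mag_annotations)
    presence = pd.DataFrame(False, index=mags, columns=cat.genes)
    for mag, tokens in mag_annotations.items():
        tokset = {t.lower() if not _KO_RE.match(str(t)) else str(t) for t in tokens}
        for strat, genes in cat.strategies.items():
            for gene in genes:
                if cat.aliases(gene) & tokset:
                    presence.loc[mag, gene] = True
    complete = pd.DataFrame(
        {
            strat: presence[list(genes)].all(axis=1)
            for strat, genes in cat.strategies.items()
        },
        index=mags,
    )
    return presence, complete
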