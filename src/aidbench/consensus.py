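"""Multi-method ancestral-sequence consensus and ambiguity-variant enumeration.

Ancestral sequence reconstruction tools (e.g. MrBayes, RAxML, ProtASR) emit
per-site posterior probabilities over amino acids for an internal tree node.
This module combines such profiles across methods as a weighted average
(by default weighting the Bayesian method twice the others), calls the
maximum-probability residue at each site, and enumerates single-substitution
variants at ambiguous sites: a site is ambiguous when the statistical
uncertainty 1 - p_max reaches the ambiguity threshold (default 0.2), and
every alternative residue whose combined probability itself reaches the
threshold becomes one variant to synthesize.

Sites are 1-based in all tables and variant labels (F209I style); internal
arrays are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AncestralPosterior",
    "AncestralConsensus",
    "Variant",
    "DEFAULT_METHOD_WEIGHTS",
    "parse_posterior_table",
    "write_posterior_table",
    "combine_methods",
    "call_consensus",
    "write_consensus",
]

logger = logging.getLogger(__name__)

#: Default combination weights: higher emphasis on the Bayesian method.
DEFAULT_METHOD_WEIGHTS: dict[str, float] = {"mrbayes": 2.0, "raxml": 1.0, "protasr": 1.0}

_SUM_TOL = 1e-3
# Threshold comparisons are >= with a tiny slack so that probabilities that
# are exactly at the threshold up to float rounding (e.g. 1 - 0.8) qualify.
_EPS = 1e-9


@dataclass
class AncestralPosterior:
    """Per-site amino-acid probability profile of one method for one node.

    ``profile[i]`` is the probability map of site i+1 (sites contiguous
    from 1..L).
    """

    method: str
    node_id: str
    profile: list[dict[str, float]]

    def __post_init__(self) -> None:
        bad = [
            i + 1
            for i, probs in enumerate(self.profile)
            if abs(sum(probs.values()) - 1.0) > _SUM_TOL or min(probs.values(), default=0) < 0
        ]
        if bad:
            raise ValueError(f"site probabilities do not sum to 1 at sites {bad}")

    def __len__(self) -> int:
        return len(self.profile)


@dataclass(frozen=True)
class Variant:
    """One single-substitution variant at an ambiguous site (1-based)."""

    site: int
    consensus_residue: str
    variant_residue: str
    probability: float

    @property
    def label(self) -> str:
        return f"{self.consensus_residue}{self.site}{self.variant_residue}"


@dataclass
class AncestralConsensus:
    """Consensus sequence, ambiguous sites, and synthesis variants for a node."""

    node_id: str
    consensus_sequence: str
    ambiguous_sites: list[tuple[int, dict[str, float]]]
    variants: list[Variant]
    method_weights: dict[str, float] = field(default_factory=dict)
    ambiguity_threshold: float = 0.2

    def variant_sequences(self) -> dict[str, str]:
        """Full-length sequence per variant, keyed by node+label."""
        out = {}
        for var in self.variants:
            seq = list(self.consensus_sequence)
            seq[var.site - 1] = var.variant_residue
            out[f"{self.node_id}_{var.label}"] = "".join(seq)
        return out


def parse_posterior_table(path: str | Path) -> list[AncestralPosterior]:
    """Read a unified posterior TSV (method, node, site, residue, probability).

    Residues absent at a site are treated as probability 0.  Each (method,
    node) pair becomes one profile; sites must be contiguous from 1 and each
    site's probabilities must sum to 1 within 1e-3.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"method", "node", "site", "residue", "probability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"posterior table missing columns: {sorted(missing)}")
    out = []
    for (method, node), grp in df.groupby(["method", "node"], sort=True):
        sites = sorted(grp["site"].unique())
        if sites != list(range(1, len(sites) + 1)):
            raise ValueError(f"{method}/{node}: sites not contiguous from 1")
        profile: list[dict[str, float]] = [{} for _ in sites]
        for _, row in grp.iterrows():
            profile[int(row["site"]) - 1][str(row["residue"])] = float(row["probability"])
        out.append(AncestralPosterior(method=str(method), node_id=str(node), profile=profile))
    return out


def write_posterior_table(posteriors: Sequence[AncestralPosterior], path: str | Path) -> None:
    """Write profiles to the unified TSV understood by parse_posterior_table."""
    rows = [
        {"method": p.method, "node": p.node_id, "site": i + 1, "residue": res, "probability": prob}
        for p in posteriors
        for i, probs in enumerate(p.profile)
        for res, prob in sorted(probs.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def combine_methods(
    posteriors: Sequence[AncestralPosterior],
    weights: Mapping[str, float] | None = None,
) -> AncestralPosterior:
    """Weighted per-site average of several methods' profiles, renormalized.

    Methods absent from ``weights`` get weight 1.  All profiles must refer
    to the same node and have the same length.
    """
    if not posteriors:
        raise ValueError("no posteriors to combine")
    if weights is None:
        weights = DEFAULT_METHOD_WEIGHTS
    nodes = {p.node_id for p in posteriors}
    if len(nodes) != 1:
        raise ValueError(f"posteriors refer to different nodes: {sorted(nodes)}")
    lengths = {len(p) for p in posteriors}
    if len(lengths) != 1:
        raise ValueError(f"profile length mismatch: {sorted(lengths)}")
    w = {p.method: float(weights.get(p.method, 1.0)) for p in posteriors}
    if any(v < 0 for v in w.values()) or sum(w.values()) == 0:
        raise ValueError("weights must be non-negative and not all zero")

    combined: list[dict[str, float]] = []
    for i in range(lengths.pop()):
        acc: dict[str, float] = {}
        for p in posteriors:
            for res, prob in p.profile[i].items():
                acc[res] = acc.get(res, 0.0) + w[p.method] * prob
        total = sum(acc.values())
        combined.append({res: v / total for res, v in acc.items()})
    return AncestralPosterior(method="combined", node_id=nodes.pop(), profile=combined)


def call_consensus(
    profile: AncestralPosterior, ambiguity_threshold: float = 0.2
) -> AncestralConsensus:
    """Call the consensus sequence and enumerate ambiguity variants.

    Consensus residue per site is the highest-probability residue (ties to
    the lexicographically first, logged).  A site is ambiguous iff
    1 - p_max >= ambiguity_threshold; at such a site each non-consensus
    residue with probability >= ambiguity_threshold yields one
    single-substitution variant.
    """
    if not 0 < ambiguity_threshold <= 1:
        raise ValueError("ambiguity threshold must lie in (0, 1]")
    consensus: list[str] = []
    ambiguous: list[tuple[int, dict[str, float]]] = []
    variants: list[Variant] = []
    for i, probs in enumerate(profile.profile):
        p_max = max(probs.values())
        top = sorted(res for res, p in probs.items() if p == p_max)
        if len(top) > 1:
            logger.info("site %d: tie among %s, calling %s", i + 1, top, top[0])
        best = top[0]
        consensus.append(best)
        if 1.0 - p_max >= ambiguity_threshold - _EPS:
            alts = {
                res: p
                for res, p in sorted(probs.items())
                if res != best and p >= ambiguity_threshold - _EPS
            }
            ambiguous.append((i + 1, dict(probs)))
            variants.extend(
                Variant(site=i + 1, consensus_residue=best, variant_residue=res, probability=p)
                for res, p in alts.items()
            )
    return AncestralConsensus(
        node_id=profile.node_id,
        consensus_sequence="".join(consensus),
        ambiguous_sites=ambiguous,
        variants=variants,
        ambiguity_threshold=ambiguity_threshold,
    )


def write_consensus(
    consensus: AncestralConsensus, fasta_path: str | Path, variants_path: str | Path
) -> None:
    """Write the consensus plus variant sequences as FASTA and a variant TSV."""
    from . import io as _io

    records = {f"{consensus.node_id}_consensus": consensus.consensus_sequence}
    records.update(consensus.variant_sequences())
    _io.write_fasta(records, fasta_path)
    pd.DataFrame(
        [
            {
                "site": v.site,
                "consensus_residue": v.consensus_residue,
                "variant_residue": v.variant_residue,
                "probability": v.probability,
            }
            for v in consensus.variants
        ],
        columns=["site", "consensus_residue", "variant_residue", "probability"],
    ).to_csv(variants_path, sep="\t", index=False)
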