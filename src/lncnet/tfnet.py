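"""Trans-regulation inference: lncRNA-TF association by target-set overlap.

Each lncRNA's co-expressed mRNA partner set is tested against each
transcription factor's regulatory-target set with the upper-tail
hypergeometric distribution; Benjamini-Hochberg FDR is controlled jointly
over all (lncRNA, TF) pairs, and a pair is accepted when p < 0.01 and
FDR < 0.01. Accepted associations, their driving overlap genes and the
underlying co-expression edges assemble a tripartite TF-lncRNA-mRNA network.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .core import GeneSetCollection, ValidationError
from .enrichment import bh_fdr, hypergeom_upper
from .io import SIF_COEXPRESSED, SIF_REGULATES

TF_COLUMNS = ["lncRNA_probe_id", "tf_id", "k", "n", "K", "M", "p_value", "fdr", "accepted"]

NODE_TF = "TF"
NODE_LNCRNA = "lncRNA"
NODE_MRNA = "mRNA"


def tf_enrichment(
    partner_sets: dict[str, frozenset[str]],
    tf_sets: GeneSetCollection,
    p_cut: float = 0.01,
    fdr_cut: float = 0.01,
    universe: frozenset[str] | None = None,
    joint_fdr: bool = True,
) -> pd.DataFrame:
    """Test every (lncRNA, TF) pair for partner/target overlap.

    The universe M defaults to all genes in the TF collection; passing the
    measured mRNA symbol set intersects it down so p-values ignore
    unmeasured genes. FDR is BH over all pairs jointly (default) or
    per-lncRNA with ``joint_fdr=False``. ``accepted`` requires both
    p < p_cut and fdr < fdr_cut.
    """
    uni = tf_sets.universe if universe is None else frozenset(universe) & tf_sets.universe
    M = len(uni)
    rows = []
    for lnc, partners in partner_sets.items():
        effective = frozenset(partners) & uni
        if not effective:
            warnings.warn(f"lncRNA {lnc!r}: no partner gene in the TF universe; skipped")
            continue
        n = len(effective)
        for tf in tf_sets.term_ids():
            targets = tf_sets.members(tf) & uni
            K = len(targets)
            k = len(effective & targets)
            p = hypergeom_upper(k, n, K, M) if K else 1.0
            rows.append((lnc, tf, k, n, K, M, p))
    df = pd.DataFrame(rows, columns=TF_COLUMNS[:7])
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        df["accepted"] = pd.Series(dtype=bool)
        return df
    if joint_fdr:
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    else:
        df["fdr"] = df.groupby("lncRNA_probe_id")["p_value"].transform(
            lambda p: bh_fdr(p.to_numpy())
        )
    df["accepted"] = (df["p_value"] < p_cut) & (df["fdr"] < fdr_cut)
    return df.sort_values(["p_value", "lncRNA_probe_id", "tf_id"]).reset_index(drop=True)


def build_tripartite_network(
    associations: pd.DataFrame,
    edges: pd.DataFrame,
    tf_sets: GeneSetCollection,
    symbol_map: dict[str, str] | None = None,
    include_unassociated_edges: bool = False,
) -> nx.Graph:
    """Assemble the TF -> lncRNA -> mRNA network from accepted associations.

    Per accepted (lncRNA, TF) pair: one TF-lncRNA edge, one TF-mRNA edge for
    each partner gene inside the TF's target set (the overlap that drove the
    association, keeping the graph legible), and the lncRNA-mRNA
    co-expression edges for that lncRNA. Node attribute ``node_class`` is
    one of TF/lncRNA/mRNA; the SIF/GraphML writer stamps degrees.
    """
    accepted = associations[associations["accepted"]]
    known = set(edges["lncRNA_probe_id"])
    unknown = sorted(set(accepted["lncRNA_probe_id"]) - known)
    if unknown:
        raise ValidationError(f"accepted association(s) reference lncRNA(s) with no edges: {unknown}")

    g = nx.Graph()
    sym = symbol_map or {}

    def mrna_symbol(probe: str) -> str:
        return sym.get(probe, probe)

    lnc_partners: dict[str, set[str]] = {}
    for lnc, mrna, r in zip(edges["lncRNA_probe_id"], edges["mRNA_probe_id"], edges["r"]):
        lnc_partners.setdefault(lnc, set()).add(mrna)

    involved_lnc = set(accepted["lncRNA_probe_id"]) if not include_unassociated_edges else known
    for lnc in sorted(involved_lnc):
        g.add_node(lnc, node_class=NODE_LNCRNA)
        for mrna in sorted(lnc_partners.get(lnc, ())):
            node = mrna_symbol(mrna)
            g.add_node(node, node_class=NODE_MRNA)
            r = float(edges.loc[
                (edges["lncRNA_probe_id"] == lnc) & (edges["mRNA_probe_id"] == mrna), "r"
            ].iloc[0])
            g.add_edge(lnc, node, interaction=SIF_COEXPRESSED, r=r)

    for row in accepted.itertuples(index=False):
        lnc, tf = row.lncRNA_probe_id, row.tf_id
        g.add_node(tf, node_class=NODE_TF)
        g.add_edge(tf, lnc, interaction=SIF_REGULATES, fdr=float(row.fdr))
        targets = tf_sets.members(tf)
        partner_symbols = {mrna_symbol(m) for m in lnc_partners.get(lnc, ())}
        for gene in sorted(partner_symbols & targets):
            g.add_node(gene, node_class=NODE_MRNA)
            g.add_edge(tf, gene, interaction=SIF_REGULATES, fdr=float(row.fdr))
    return g


def hub_ranking(graph: nx.Graph) -> list[tuple[str, int]]:
    """TFs sorted by degree descending (ties by id) — the network's hubs."""
    tfs = [n for n, d in graph.nodes(data=True) if d.get("node_class") == NODE_TF]
    return sorted(((tf, graph.degree(tf)) for tf in tfs), key=lambda x: (-x[1], x[0]))
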