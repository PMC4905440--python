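"""Bundled worked example: top differentially expressed probes from an
atrial fibrillation blood microarray study (3 AF vs 3 control samples).

Two tables ship with the package, each with 25 probes: the top lncRNAs and
the top mRNAs, carrying the published per-sample log2 intensities alongside
the published absolute fold change, p-value and regulation direction. They
serve as an exact regression fixture for the screening stage: recomputing
fold change and pooled t-test p from the six intensities reproduces the
published columns.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .core import CASE, CONTROL, LNCRNA, MRNA, ExpressionMatrix, ProbeAnnotation

SAMPLE_COLUMNS = ["N1", "N2", "N3", "AF1", "AF2", "AF3"]
GROUP_MAP = {"N1": CONTROL, "N2": CONTROL, "N3": CONTROL,
             "AF1": CASE, "AF2": CASE, "AF3": CASE}


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("lncnet.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"probe_id": str})


def load_af_lncRNA_table() -> pd.DataFrame:
    """The 25-row lncRNA worked-example table (intensities + published stats)."""
    return _load("af_top_lncRNA.tsv")


def load_af_mRNA_table() -> pd.DataFrame:
    """The 25-row mRNA worked-example table (intensities + published stats)."""
    return _load("af_top_mRNA.tsv")


def load_af_worked_example() -> tuple[ExpressionMatrix, ProbeAnnotation, pd.DataFrame]:
    """Assemble the 50-probe expression matrix, annotation and reference table.

    Returns the matrix of log2 intensities (N1-N3 control, AF1-AF3 case), a
    probe annotation (molecule class, gene symbol where published, lncRNA
    coordinates where published), and the published reference columns
    (``fc_abs``, ``p``, ``regulation``) indexed like the matrix.
    """
    lnc = load_af_lncRNA_table()
    mrna = load_af_mRNA_table()

    values = pd.concat(
        [lnc.set_index("probe_id")[SAMPLE_COLUMNS],
         mrna.set_index("probe_id")[SAMPLE_COLUMNS]]
    )
    matrix = ExpressionMatrix(values, dict(GROUP_MAP))

    n_l, n_m = len(lnc), len(mrna)
    ann = pd.DataFrame({
        "probe_id": [*lnc["probe_id"], *mrna["probe_id"]],
        "molecule_class": [LNCRNA] * n_l + [MRNA] * n_m,
        "gene_symbol": [None] * n_l + [
            s if isinstance(s, str) and s else None for s in mrna["gene_symbol"]
        ],
        "chrom": [*lnc["chrom"].where(lnc["chrom"].notna(), None), *([None] * n_m)],
        "start": [*lnc["start"].where(lnc["start"].notna(), None), *([None] * n_m)],
        "end": [*lnc["end"].where(lnc["end"].notna(), None), *([None] * n_m)],
    })
    annotation = ProbeAnnotation(ann)

    reference = pd.concat(
        [lnc.set_index("probe_id")[["fc_abs", "p", "regulation"]],
         mrna.set_index("probe_id")[["fc_abs", "p", "regulation"]]]
    )
    return matrix, annotation, reference
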