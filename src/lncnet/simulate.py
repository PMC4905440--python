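"""Synthetic two-group microarray data with planted, recoverable structure.

The generator emulates a case/control log2-intensity array experiment at
desk scale: per-probe Gaussian baselines, within-group Gaussian noise,
planted differential probes (a 50/50 up/down split of a fixed log2 shift),
planted lncRNA-mRNA co-expression modules driven by a shared per-sample
latent factor, and transcription-factor target sets enriched for their
matched module's mRNAs. Truth tables accompany every dataset so each
downstream stage can be scored against what was planted.

Module members take the value mu_p + beta * z_{m,s} + eps with z the
module's latent factor and eps ~ Normal(0, module_noise_sd); the default
beta/module_noise_sd ratio of 20 puts the population pairwise correlation at
beta^2/(beta^2 + sigma^2) ~ 0.9975, inside the extreme |r| >= 0.99 regime
the co-expression stage thresholds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CASE,
    CONTROL,
    LNCRNA,
    MRNA,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    QPCRRecord,
    ValidationError,
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a realistic desk-scale study.

    Intensities are log2-scale throughout; ``de_shift`` is the planted
    |Δmean| in log2 units (2.5 ~ a 5.7-fold change, the regime of the top
    published probes). ``module_size`` is (lncRNAs, mRNAs) per module.
    Of ``n_tf`` target sets the first ``min(n_modules, n_tf)`` are matched
    to modules; the remainder are decoys of random mRNAs.
    """

    n_lncRNA: int = 1000
    n_mRNA: int = 1000
    n_per_group: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.5
    noise_sd: float = 0.5
    n_de_lncRNA: int = 100
    n_de_mRNA: int = 100
    de_shift: float = 2.5
    n_modules: int = 3
    module_size: tuple[int, int] = (3, 10)
    module_beta: float = 3.0
    module_noise_sd: float = 0.15
    n_tf: int = 8
    tf_set_size: int = 40
    tf_target_frac_in_module: float = 0.9
    frac_shared_symbols: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_lncRNA, self.n_mRNA, self.n_per_group, self.n_de_lncRNA,
                  self.n_de_mRNA, self.n_modules, self.n_tf, self.tf_set_size)
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if self.noise_sd <= 0 or self.module_noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValidationError("standard deviations must be > 0")
        lnc_needed = self.n_de_lncRNA + self.n_modules * self.module_size[0]
        mrna_needed = self.n_de_mRNA + self.n_modules * self.module_size[1]
        if lnc_needed > self.n_lncRNA or mrna_needed > self.n_mRNA:
            raise ValidationError(
                "planted DE + module probes exceed totals "
                f"(need {lnc_needed} lncRNA / {mrna_needed} mRNA)"
            )
        if not 0.0 <= self.tf_target_frac_in_module <= 1.0:
            raise ValidationError("tf_target_frac_in_module must be in [0, 1]")


@dataclass
class SimTruth:
    """What was planted: DE probes, module memberships, TF matching."""

    de: pd.DataFrame        # probe_id, molecule_class, direction, shift
    modules: pd.DataFrame   # module_id, probe_id, molecule_class, gene_symbol
    tf_match: dict[str, str] = field(default_factory=dict)  # tf_id -> module_id

    def de_ids(self) -> set[str]:
        return set(self.de["probe_id"])

    def module_members(self, module_id: str, molecule_class: str | None = None) -> list[str]:
        m = self.modules[self.modules["module_id"] == module_id]
        if molecule_class is not None:
            m = m[m["molecule_class"] == molecule_class]
        return m["probe_id"].tolist()

    def module_mrna_symbols(self, module_id: str) -> frozenset[str]:
        m = self.modules[
            (self.modules["module_id"] == module_id)
            & (self.modules["molecule_class"] == MRNA)
        ]
        return frozenset(m["gene_symbol"])


def _symbols(n_mrna: int, frac_shared: float, rng: np.random.Generator) -> list[str]:
    n_distinct = max(1, round(n_mrna * (1.0 - frac_shared)))
    pool = [f"GENE{i:05d}" for i in range(n_distinct)]
    out = list(pool)
    extra = n_mrna - n_distinct
    if extra > 0:
        out += list(rng.choice(pool, size=extra, replace=True))
    rng.shuffle(out)
    return out


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, ProbeAnnotation, SimTruth]:
    """Draw one dataset; identical cfg (incl. seed) gives identical output.

    Planted DE probes get exactly +/- de_shift added to every case sample,
    so their population Δmean is the shift by construction. Module members
    are drawn disjoint from DE probes and their within-group noise is
    module_noise_sd around the shared latent factor.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_s = cfg.n_per_group
    lnc_ids = [f"LNC{i:05d}" for i in range(cfg.n_lncRNA)]
    mrna_ids = [f"MRNA{i:05d}" for i in range(cfg.n_mRNA)]
    probes = lnc_ids + mrna_ids
    classes = [LNCRNA] * cfg.n_lncRNA + [MRNA] * cfg.n_mRNA
    samples = [f"N{i+1}" for i in range(n_s)] + [f"AF{i+1}" for i in range(n_s)]
    groups = {s: (CONTROL if s.startswith("N") else CASE) for s in samples}
    n_probes, n_cols = len(probes), 2 * n_s

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_probes)
    values = mu[:, None] + rng.normal(0.0, cfg.noise_sd, (n_probes, n_cols))

    # planted DE: first the lncRNAs, then the mRNAs, sign split 50/50
    de_rows = []
    case_cols = slice(n_s, n_cols)
    for offset, count, cls in ((0, cfg.n_de_lncRNA, LNCRNA), (cfg.n_lncRNA, cfg.n_de_mRNA, MRNA)):
        idx = offset + rng.choice(
            cfg.n_lncRNA if cls == LNCRNA else cfg.n_mRNA, size=count, replace=False
        )
        signs = np.where(np.arange(count) % 2 == 0, 1.0, -1.0)
        rng.shuffle(signs)
        for i, s in zip(idx, signs):
            values[i, case_cols] += s * cfg.de_shift
            de_rows.append((probes[i], cls, "up" if s > 0 else "down", s * cfg.de_shift))
    de = pd.DataFrame(de_rows, columns=["probe_id", "molecule_class", "direction", "shift"])

    # planted modules on probes disjoint from the DE set
    symbols = _symbols(cfg.n_mRNA, cfg.frac_shared_symbols, rng)
    symbol_of = dict(zip(mrna_ids, symbols))
    de_idx = {probes.index(p) for p in de["probe_id"]}
    free_lnc = [i for i in range(cfg.n_lncRNA) if i not in de_idx]
    free_mrna = [i + cfg.n_lncRNA for i in range(cfg.n_mRNA) if i + cfg.n_lncRNA not in de_idx]
    mod_rows = []
    size_l, size_m = cfg.module_size
    pick_l = rng.choice(len(free_lnc), size=cfg.n_modules * size_l, replace=False)
    pick_m = rng.choice(len(free_mrna), size=cfg.n_modules * size_m, replace=False)
    for m in range(cfg.n_modules):
        module_id = f"MOD{m:02d}"
        z = rng.normal(0.0, 1.0, n_cols)
        members = [free_lnc[i] for i in pick_l[m * size_l:(m + 1) * size_l]] + [
            free_mrna[i] for i in pick_m[m * size_m:(m + 1) * size_m]
        ]
        for i in members:
            values[i, :] = mu[i] + cfg.module_beta * z + rng.normal(
                0.0, cfg.module_noise_sd, n_cols
            )
            cls = classes[i]
            mod_rows.append((module_id, probes[i], cls,
                             symbol_of.get(probes[i]) if cls == MRNA else None))
    modules = pd.DataFrame(
        mod_rows, columns=["module_id", "probe_id", "molecule_class", "gene_symbol"]
    )

    matrix = ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), groups)
    annotation = ProbeAnnotation(pd.DataFrame({
        "probe_id": probes,
        "molecule_class": classes,
        "gene_symbol": [None] * cfg.n_lncRNA + [symbol_of[p] for p in mrna_ids],
    }))
    return matrix, annotation, SimTruth(de=de, modules=modules)


def simulate_tf_gmt(cfg: SimulationConfig, truth: SimTruth) -> GeneSetCollection:
    """TF target sets over the simulated mRNA symbols.

    The first min(n_modules, n_tf) TFs are matched: each takes
    ``tf_target_frac_in_module`` of its module's mRNA symbols plus random
    off-module symbols up to ``tf_set_size``. Remaining TFs are decoys of
    purely random symbols. Deterministic given cfg and truth; records the
    matching in ``truth.tf_match``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    all_symbols = sorted({f"GENE{i:05d}" for i in range(
        max(1, round(cfg.n_mRNA * (1.0 - cfg.frac_shared_symbols)))
    )})
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    truth.tf_match = {}
    module_ids = sorted(truth.modules["module_id"].unique())
    for t in range(cfg.n_tf):
        tf_id = f"TF{t:02d}"
        members: set[str] = set()
        if t < len(module_ids):
            module = module_ids[t]
            mod_symbols = sorted(truth.module_mrna_symbols(module))
            n_in = round(cfg.tf_target_frac_in_module * len(mod_symbols))
            members |= set(rng.choice(mod_symbols, size=n_in, replace=False)) if n_in else set()
            truth.tf_match[tf_id] = module
        pool = [s for s in all_symbols if s not in members]
        n_fill = max(0, cfg.tf_set_size - len(members))
        members |= set(rng.choice(pool, size=min(n_fill, len(pool)), replace=False))
        desc = f"targets of simulated factor {tf_id}"
        sets[tf_id] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def simulate_functional_gmt(
    cfg: SimulationConfig, annotation: ProbeAnnotation, n_terms: int = 20,
    term_size: int = 50,
) -> GeneSetCollection:
    """Random functional term sets over the simulated mRNA symbols (null terms)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    symbols = sorted(set(annotation.symbol_map().values()))
    sets = {
        f"TERM{t:03d}": (
            f"simulated functional term {t}",
            frozenset(rng.choice(symbols, size=min(term_size, len(symbols)), replace=False)),
        )
        for t in range(n_terms)
    }
    return GeneSetCollection(sets)


def simulate_qpcr(
    n_case: int,
    n_control: int,
    true_log2_ratio: float,
    ct_sd: float = 0.3,
    seed: int = 0,
    n_replicates: int = 3,
) -> list[QPCRRecord]:
    """Simulate Ct tables with a planted case/control log2 expression ratio.

    Each sample has a reference level ~ Normal(20, ct_sd); target replicates
    sit a fixed offset above it, minus ``true_log2_ratio`` cycles for case
    samples (higher expression = earlier threshold = lower Ct), so the
    expected case RQ is exactly 2^true_log2_ratio. Replicate noise is
    Normal(0, ct_sd). As ct_sd -> 0 the arithmetic becomes exact.
    """
    if n_case < 1 or n_control < 1:
        raise ValidationError("need >= 1 sample per group")
    rng = np.random.default_rng(seed)
    offset = 5.0
    records = []
    for group, count, prefix in ((CONTROL, n_control, "N"), (CASE, n_case, "AF")):
        effect = true_log2_ratio if group == CASE else 0.0
        for i in range(count):
            base = rng.normal(20.0, ct_sd) if ct_sd > 0 else 20.0
            noise = lambda: (rng.normal(0.0, ct_sd, n_replicates) if ct_sd > 0
                             else np.zeros(n_replicates))
            ref = base + noise()
            tgt = base + offset - effect + noise()
            records.append(QPCRRecord(
                sample_id=f"{prefix}{i+1}", group=group,
                target_ct=tuple(tgt), reference_ct=tuple(ref),
            ))
    return records
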