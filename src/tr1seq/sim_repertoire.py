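"""Synthetic paired-chain single-cell TCR repertoire generator.

Emulates the structure of a pMHCII-nanomedicine study repertoire: five
cell pools (a tetramer-negative conventional pool ``Tconv``, three
insulin-register tetramer+ pools ``R1``/``R2``/``R3``, and a ``BDC``
mimotope pool), each an oligoclonal mixture of paired alpha/beta clones
with pool-specific V/J usage skew, controllable charged-residue motifs at
CDR3beta positions 2-3, and an optional "low-avidity leak" that copies
whole repeated tetramer+ clonotypes into the Tconv pool.

Every cell's contigs are (optionally noisy) concatenations of its clone's
germline V, a non-templated junction and the germline J, productive by
construction: junctions are drawn in codon units so the conserved V
cysteine and J phenylalanine/tryptophan anchors stay in frame, and codons
are sampled from the 61 sense codons so no stop interrupts the CDR3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .germline import ACIDIC_CODONS, SENSE_CODONS, GermlineSegment, _segments_by

POOLS = ("Tconv", "R1", "R2", "R3", "BDC")

#: per-pool cell counts; tetramer+ pools sized to the study's sequenced
#: paired-TCR counts, Tconv/BDC to their QC-passing cell counts
DEFAULT_N_CELLS = {"Tconv": 181, "R1": 144, "R2": 94, "R3": 155, "BDC": 190}

#: geometric clone-size parameter per pool (mean clone size = 1/p); R1 is
#: mostly unique (~114 clonotypes among 144 cells) while R2/R3 are
#: markedly more clonal (~13 and ~9 expected singletons in 94 and 155
#: cells respectively, since E[singletons] ~ n p^2 for a geometric mix)
DEFAULT_CLONE_SIZE_P = {"Tconv": 0.9, "R1": 0.8, "R2": 0.37, "R3": 0.24, "BDC": 0.3}

#: expected fraction of chains using the focal germline elements, from the
#: per-pool chain counts reported for TRAV5D-4, TRAJ18 and TRBV1
DEFAULT_USAGE_FRACTION: dict[str, dict[str, float]] = {
    "Tconv": {"TRAV5D-4": 0.107, "TRAJ18": 0.076, "TRBV1": 0.103},
    "R1": {"TRAV5D-4": 0.175, "TRAJ18": 0.091, "TRBV1": 0.050},
    "R2": {"TRAV5D-4": 0.403, "TRAJ18": 0.186, "TRBV1": 0.200},
    "R3": {"TRAV5D-4": 0.425, "TRAJ18": 0.265, "TRBV1": 0.671},
    "BDC": {"TRAV5D-4": 0.100, "TRAJ18": 0.080, "TRBV1": 0.100},
}

#: probability that a clonotype carries Asp/Glu at CDR3beta P2 or P3; the
#: tetramer+ pools use the reported clonotype fractions, Tconv/BDC a
#: neutral background rate
DEFAULT_CHARGED_MOTIF_PROB = {
    "Tconv": 0.15,
    "R1": 0.372,
    "R2": 0.101,
    "R3": 0.512,
    "BDC": 0.20,
}

#: probability a tetramer+ cell sits in the TR1-like cluster (2) rather
#: than the TFH-like cluster (1); Tconv cells sit in cluster 0
DEFAULT_CLUSTER2_FRACTION = 0.65


@dataclass
class RepertoireConfig:
    """Study conditions for the repertoire generator."""

    n_cells: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_CELLS))
    clone_size_p: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLONE_SIZE_P)
    )
    usage_fraction: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_USAGE_FRACTION.items()}
    )
    charged_motif_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGED_MOTIF_PROB)
    )
    cluster2_fraction: float = DEFAULT_CLUSTER2_FRACTION
    #: junction length in codons: min + geometric(p), capped so the
    #: nucleotide junction never exceeds the 50-nt junction cap
    junction_min_codons: int = 2
    junction_geometric_p: float = 0.35
    junction_max_codons: int = 16
    error_rate: float = 0.0
    #: probability that a repeated clonotype of ``leak_source_pool`` also
    #: appears (1-2 cells) in the Tconv gate; the default reproduces the
    #: order of ~10 low-avidity clonotypes seen in both gates
    leak_rate: float = 0.4
    leak_source_pool: str = "R1"
    #: clonotypes present in both the R2 and R3 pools (register shifting
    #: of the longer R3 epitope makes a few clones cross-reactive)
    shared_r2_r3: int = 2

    def validate(self) -> None:
        for pool, n in self.n_cells.items():
            if pool not in POOLS:
                raise ParameterError(f"unknown pool {pool!r}")
            if n < 0:
                raise ParameterError(f"n_cells[{pool}] must be >= 0")
        for pool, p in self.clone_size_p.items():
            if not 0 < p <= 1:
                raise ParameterError(f"clone_size_p[{pool}] must be in (0, 1]")
        for pool, p in self.charged_motif_prob.items():
            if not 0 <= p <= 1:
                raise ParameterError(f"charged_motif_prob[{pool}] must be in [0, 1]")
        for pool, frac in self.usage_fraction.items():
            for name, f in frac.items():
                if not 0 <= f < 1:
                    raise ParameterError(f"usage fraction for {name} must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must be in [0, 1)")
        if not 0 <= self.leak_rate <= 1:
            raise ParameterError("leak_rate must be in [0, 1]")
        if self.shared_r2_r3 < 0:
            raise ParameterError("shared_r2_r3 must be >= 0")
        if not 0 <= self.cluster2_fraction <= 1:
            raise ParameterError("cluster2_fraction must be in [0, 1]")
        if self.junction_min_codons < 2:
            # P2 and P3 must be junction-encoded for exact motif control
            raise ParameterError("junction_min_codons must be >= 2")
        if 3 * self.junction_max_codons > 50:
            raise ParameterError("junction cap exceeds 50 nt")


@dataclass
class RepertoireTruth:
    """Ground truth of one simulated repertoire.

    ``cells``: one row per cell (cell_id, pool, clone_id, true_cluster).
    ``contigs``: one row per chain per cell (cell_id, chain, sequence).
    ``clone_table``: one row per clone with its germline/junction identity,
    size, charged-motif truth and cluster-assignment probabilities.
    """

    cells: pd.DataFrame
    contigs: pd.DataFrame
    clone_table: pd.DataFrame

    def contigs_of(self, cell_id: str) -> list[tuple[str, str]]:
        sub = self.contigs[self.contigs.cell_id == cell_id]
        return list(zip(sub.chain, sub.sequence))


def _usage_weights(
    names: list[str], targets: dict[str, float]
) -> np.ndarray:
    """Per-element probabilities hitting the target fraction for named
    elements exactly, uniform over the rest."""
    named = {n: f for n, f in targets.items() if n in names}
    rest = [n for n in names if n not in named]
    spare = 1.0 - sum(named.values())
    if spare < 0 or (not rest and spare > 1e-9):
        raise ParameterError(
            f"usage fractions for one locus sum past 1: {sorted(named)}"
        )
    w = np.empty(len(names))
    for i, n in enumerate(names):
        w[i] = named[n] if n in named else spare / len(rest)
    return w / w.sum()


def _draw_clone_sizes(rng: np.random.Generator, n: int, p: float) -> list[int]:
    sizes: list[int] = []
    remaining = n
    while remaining > 0:
        s = min(int(rng.geometric(p)), remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def _draw_junction(
    rng: np.random.Generator,
    cfg: RepertoireConfig,
    forced_motif: bool | None = None,
) -> str:
    """A junction as whole sense codons; ``forced_motif`` pins the
    presence/absence of Asp/Glu at the first two junction codons (CDR3
    P2/P3, position 1 being the V cysteine)."""
    n_codons = min(
        cfg.junction_min_codons + int(rng.geometric(cfg.junction_geometric_p)) - 1,
        cfg.junction_max_codons,
    )
    while True:
        codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
        if forced_motif is True:
            pos = int(rng.integers(0, 2))
            codons[pos] = sorted(ACIDIC_CODONS)[int(rng.integers(0, len(ACIDIC_CODONS)))]
            return "".join(codons)
        has = codons[0] in ACIDIC_CODONS or codons[1] in ACIDIC_CODONS
        if forced_motif is None or has is False:
            if forced_motif is False and has:
                continue
            return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_repertoire(
    germline: list[GermlineSegment],
    config: RepertoireConfig | None = None,
    seed: int = 0,
) -> RepertoireTruth:
    """Simulate an oligoclonal paired-chain repertoire under ``config``.

    Distinct clones are guaranteed distinct paired (V, junction, J)
    identifiers, so with zero error rate the clonal partition is exactly
    recoverable by string equality downstream.
    """
    cfg = config or RepertoireConfig()
    cfg.validate()
    if not germline:
        raise ParameterError("empty germline")
    rng = np.random.default_rng(seed)

    seg = {
        (chain, cls): _segments_by(germline, chain, cls)
        for chain in ("alpha", "beta")
        for cls in ("V", "J")
    }
    for key, lst in seg.items():
        if not lst:
            raise ParameterError(f"germline lacks segments for {key}")

    clone_rows: list[dict] = []
    cell_rows: list[dict] = []
    contig_rows: list[dict] = []
    seen_ids: set[tuple[str, ...]] = set()
    clone_counter = 0
    cell_counter = 0

    def make_clone(pool: str, size: int) -> dict:
        nonlocal clone_counter
        motif = bool(rng.random() < cfg.charged_motif_prob.get(pool, 0.0))
        while True:
            parts = {}
            for chain in ("alpha", "beta"):
                vs, js = seg[(chain, "V")], seg[(chain, "J")]
                vnames = [s.name for s in vs]
                jnames = [s.name for s in js]
                targets = cfg.usage_fraction.get(pool, {})
                v = vs[int(rng.choice(len(vs), p=_usage_weights(vnames, targets)))]
                j = js[int(rng.choice(len(js), p=_usage_weights(jnames, targets)))]
                junction = _draw_junction(
                    rng, cfg, forced_motif=motif if chain == "beta" else None
                )
                parts[chain] = (v, junction, j)
            ident = tuple(
                sorted(
                    f"{v.name}-{jn}-{j.name}" for (v, jn, j) in parts.values()
                )
            )
            if ident not in seen_ids:
                seen_ids.add(ident)
                break
        clone_counter += 1
        return {
            "clone_id": f"clone{clone_counter:04d}",
            "pool": pool,
            "v_alpha": parts["alpha"][0].name,
            "junction_alpha": parts["alpha"][1],
            "j_alpha": parts["alpha"][2].name,
            "v_beta": parts["beta"][0].name,
            "junction_beta": parts["beta"][1],
            "j_beta": parts["beta"][2].name,
            "size": size,
            "charged_p2p3": motif,
            "p_cluster1": 0.0 if pool == "Tconv" else 1 - cfg.cluster2_fraction,
            "p_cluster2": 0.0 if pool == "Tconv" else cfg.cluster2_fraction,
            "leaked": False,
            "_parts": parts,
        }

    def add_cell(clone: dict, pool: str) -> None:
        nonlocal cell_counter
        cell_counter += 1
        cell_id = f"cell{cell_counter:04d}"
        if pool == "Tconv":
            cluster = 0
        else:
            cluster = 2 if rng.random() < cfg.cluster2_fraction else 1
        cell_rows.append(
            {
                "cell_id": cell_id,
                "pool": pool,
                "clone_id": clone["clone_id"],
                "true_cluster": cluster,
            }
        )
        for chain in ("alpha", "beta"):
            v, junction, j = clone["_parts"][chain]
            seqn = _mutate(rng, v.sequence + junction + j.sequence, cfg.error_rate)
            contig_rows.append({"cell_id": cell_id, "chain": chain, "sequence": seqn})

    for pool in POOLS:
        n = cfg.n_cells.get(pool, 0)
        if n == 0:
            continue
        sizes = _draw_clone_sizes(rng, n, cfg.clone_size_p.get(pool, 1.0))
        # register-shifting cross-reactivity: the first few R3 clones
        # reuse the identity of an R2 clone, so both pools observe them
        reuse: list[dict] = []
        if pool == "R3" and cfg.shared_r2_r3 > 0:
            r2_clones = [c for c in clone_rows if c["pool"] == "R2"]
            k = min(cfg.shared_r2_r3, len(r2_clones), len(sizes))
            if k > 0:
                picks = rng.choice(len(r2_clones), size=k, replace=False)
                reuse = [r2_clones[int(i)] for i in picks]
        for s_i, size in enumerate(sizes):
            if s_i < len(reuse):
                clone = reuse[s_i]
            else:
                clone = make_clone(pool, size)
                clone_rows.append(clone)
            for _ in range(size):
                add_cell(clone, pool)

    # low-avidity leak: whole repeated clonotypes re-observed in the Tconv gate
    if cfg.leak_rate > 0:
        for clone in clone_rows:
            if clone["pool"] != cfg.leak_source_pool or clone["size"] < 2:
                continue
            if rng.random() < cfg.leak_rate:
                clone["leaked"] = True
                for _ in range(int(rng.integers(1, 3))):
                    add_cell(clone, "Tconv")

    clone_df = pd.DataFrame([{k: v for k, v in c.items() if k != "_parts"} for c in clone_rows])
    cells_df = pd.DataFrame(cell_rows)
    # leak cells extend clone sizes
    if not cells_df.empty:
        sizes = cells_df.groupby("clone_id").size()
        clone_df["size"] = clone_df["clone_id"].map(sizes).astype(int)
    return RepertoireTruth(
        cells=cells_df,
        contigs=pd.DataFrame(contig_rows, columns=["cell_id", "chain", "sequence"]),
        clone_table=clone_df,
    )
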