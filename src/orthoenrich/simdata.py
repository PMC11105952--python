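"""Synthetic mapping tables, orthology tables, gene-set collections, and
differential-expression tables with planted enrichment.

The generators emulate the structural features the statistical machinery
must cope with — many-to-many orthology from the teleost whole-genome
duplication (a human gene has 0, 1 or 2 zebrafish co-orthologs), gene sets
of realistic pathway size, and DE p-values that are Uniform(0,1) under the
null and stochastically small, Beta(a, 1) with a < 1, inside planted sets.
They make every statistical operation testable with no external download,
and a calibration harness measures type-I error and power by repeated
simulation.

All generators are seed-deterministic: one integer seed drives independent
substreams per artifact (and per replicate), so changing the number of
sets never perturbs the gene-level draws.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .idmap import MappingTable, Namespace, OrthologyTable
from .genesets import AnnotationOrganism, GeneSet, GeneSetCollection, write_gmt
from .enrich import (
    Correction,
    DETable,
    Direction,
    Method,
    enrich_collection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedSet",
    "SimConfig",
    "gen_mapping_table",
    "gen_orthology",
    "gen_collection",
    "gen_de_table",
    "CalibrationResult",
    "calibration_run",
    "write_fixtures",
    "zfish_universe",
    "human_universe",
]


@dataclass(frozen=True)
class PlantedSet:
    """A gene set carrying planted differential-expression signal.

    ``effect`` is the Beta shape parameter a in (0, 1]: member p-values are
    drawn Beta(a, 1), so smaller a means stronger signal and a = 1 recovers
    the Uniform null."""

    set_id: str
    effect: float
    direction: Direction = Direction.UP

    def __post_init__(self):
        if not (0 < self.effect <= 1):
            raise ValueError("effect must lie in (0, 1]")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 2,000-gene zebrafish universe and 200 pathway-sized
    sets; 35% of human genes lack a zebrafish ortholog (matching the ~65%
    orthology coverage of the human protein-coding genome) and 30% carry
    two co-orthologs from the teleost duplication.
    """

    n_zfish_genes: int = 2000
    n_human_genes: int = 2000
    p_no_ortholog: float = 0.35
    p_two_orthologs: float = 0.30
    n_sets: int = 200
    set_size_range: tuple[int, int] = (20, 100)
    planted_sets: tuple[PlantedSet, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_no_ortholog, self.p_two_orthologs):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_no_ortholog + self.p_two_orthologs > 1:
            raise ValueError("p_no_ortholog + p_two_orthologs must be <= 1")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("set_size_range must satisfy 1 <= min <= max")
        self.planted_sets = tuple(self.planted_sets)


_STREAMS = {"mapping": 0, "orthology": 1, "collection": 2, "de": 3}


def _rng(cfg: SimConfig, stream: str, *extra: int) -> np.random.Generator:
    key = (_STREAMS[stream],) + tuple(extra)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def zfish_universe(cfg: SimConfig) -> list[str]:
    """Primary (symbol-namespace) zebrafish gene identifiers."""
    return [f"zfg{i + 1}" for i in range(cfg.n_zfish_genes)]


def human_universe(cfg: SimConfig) -> list[str]:
    return [f"HSG{j + 1}" for j in range(cfg.n_human_genes)]


def gen_mapping_table(cfg: SimConfig) -> MappingTable:
    """Bijective four-namespace table over the synthetic zebrafish genes."""
    n = cfg.n_zfish_genes
    frame = pd.DataFrame(
        {
            "ncbi": [str(100001 + i) for i in range(n)],
            "ensembl": [f"ENSDARG{i + 1:011d}" for i in range(n)],
            "zfin": [f"ZDB-GENE-SIM-{i + 1:06d}" for i in range(n)],
            "symbol": zfish_universe(cfg),
        }
    )
    return MappingTable(frame)


def gen_orthology(cfg: SimConfig) -> OrthologyTable:
    """Orthology table with teleost-duplication structure.

    Each human gene independently receives 0 zebrafish orthologs with
    probability ``p_no_ortholog``, 2 with probability ``p_two_orthologs``,
    else 1; partners are drawn uniformly from the zebrafish universe.
    """
    rng = _rng(cfg, "orthology")
    zfish = zfish_universe(cfg)
    rows: list[tuple[str, str]] = []
    u = rng.random(cfg.n_human_genes)
    for j, hgene in enumerate(human_universe(cfg)):
        if u[j] < cfg.p_no_ortholog:
            continue
        k = 2 if u[j] < cfg.p_no_ortholog + cfg.p_two_orthologs else 1
        partners = rng.choice(cfg.n_zfish_genes, size=k, replace=False)
        rows.extend((zfish[z], hgene) for z in partners)
    frame = pd.DataFrame(rows, columns=["zfish_id", "human_id"])
    return OrthologyTable(frame, zfish_ns=Namespace.SYMBOL, human_ns=Namespace.SYMBOL)


def gen_collection(
    cfg: SimConfig,
    universe: Sequence[str] | None = None,
    prefix: str = "dre",
) -> GeneSetCollection:
    """Synthetic KEGG-style collection: ``n_sets`` sets with sizes uniform
    in ``set_size_range`` and members sampled without replacement."""
    rng = _rng(cfg, "collection")
    if universe is None:
        universe = zfish_universe(cfg)
    universe = np.asarray(universe, dtype=object)
    lo, hi = cfg.set_size_range
    if hi > len(universe):
        raise ValueError("set sizes exceed universe size")
    organism = (
        AnnotationOrganism.ZEBRAFISH if prefix == "dre" else AnnotationOrganism.HUMAN
    )
    sizes = rng.integers(lo, hi + 1, size=cfg.n_sets)
    sets = []
    for i in range(cfg.n_sets):
        members = rng.choice(universe, size=int(sizes[i]), replace=False)
        sets.append(
            GeneSet(
                set_id=f"{prefix}9{i + 1:04d}",
                name=f"synthetic pathway {i + 1}",
                members=frozenset(members.tolist()),
                annotation_organism=organism,
            )
        )
    return GeneSetCollection(sets, namespace=Namespace.SYMBOL, organism=organism)


def gen_de_table(
    cfg: SimConfig,
    universe: Sequence[str] | None = None,
    collection: GeneSetCollection | None = None,
    rep: int = 0,
) -> DETable:
    """Differential-expression table over the universe.

    Non-planted genes draw p ~ Uniform(0,1) with a fair-coin fold-change
    sign; genes of a planted set draw p ~ Beta(a, 1) and match the planted
    direction's sign with probability 0.9.  Overlapping planted sets are
    resolved by later plantings overriding earlier ones (logged).
    """
    rng = _rng(cfg, "de", rep)
    if universe is None:
        universe = zfish_universe(cfg)
    genes = list(universe)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    pvalues = rng.random(n)
    log2fc = rng.choice([-1.0, 1.0], size=n) * np.abs(rng.normal(0.0, 1.0, size=n))

    if cfg.planted_sets:
        if collection is None:
            raise ValueError("planted sets require the collection they live in")
        already: set[str] = set()
        for planted in cfg.planted_sets:
            geneset = collection.get(planted.set_id)
            member_genes = [g for g in sorted(geneset.members) if g in index]
            overlap = already.intersection(member_genes)
            if overlap:
                logger.info(
                    "planted set %s overlaps %d previously planted genes; "
                    "later planting overrides", planted.set_id, len(overlap),
                )
            already.update(member_genes)
            idx = np.array([index[g] for g in member_genes], dtype=int)
            m = len(idx)
            pvalues[idx] = rng.beta(planted.effect, 1.0, size=m)
            sign = 1.0 if planted.direction == Direction.UP else -1.0
            match = rng.random(m) < 0.9
            magnitude = np.abs(rng.normal(1.0, 0.5, size=m))
            log2fc[idx] = np.where(match, sign, -sign) * magnitude

    frame = pd.DataFrame({"gene": genes, "pvalue": pvalues, "log2fc": log2fc})
    return DETable(frame)


@dataclass(frozen=True)
class CalibrationResult:
    """Monte-Carlo calibration summary.

    ``type_I_rate`` is the mean over replicates of the per-replicate
    fraction of non-planted sets with raw p < alpha; its standard error is
    taken across replicates (sets within a replicate share a universe and
    are correlated, so the replicate is the Monte-Carlo unit).
    """

    type_I_rate: float
    type_I_se: float
    power: dict[str, float]
    direction_recovery: float  # fraction of detections matching the planted sign
    n_detections: int
    reps: int


def calibration_run(
    cfg: SimConfig,
    method: str | Method = Method.LOGISTIC,
    alpha: float = 0.05,
    reps: int = 500,
    sig_threshold: float = 0.05,
) -> CalibrationResult:
    """Repeatedly simulate DE tables and measure test calibration.

    Type-I error uses the nondirectional test on non-planted sets; power
    and direction recovery (when sets are planted) use the up and down
    directional tests, a set counting as detected when its smaller
    directional raw p-value is below ``alpha`` and its inferred direction
    being the one with the smaller p-value.
    """
    if reps < 50:
        warnings.warn("fewer than 50 replicates: Monte-Carlo error will be large")
    method = Method(method)
    universe = zfish_universe(cfg)
    coll = gen_collection(cfg, universe)
    planted = {ps.set_id: ps for ps in cfg.planted_sets}
    null_fracs = []
    detections = {sid: 0 for sid in planted}
    n_match = 0
    n_detect = 0
    for rep in range(reps):
        de = gen_de_table(cfg, universe, coll, rep=rep)
        nd = enrich_collection(
            de, coll, method, Direction.NONDIRECTIONAL,
            sig_threshold=sig_threshold, correction=Correction.NONE,
        )
        null_p = nd.loc[~nd["set_id"].isin(planted), "pvalue"]
        null_fracs.append(float((null_p < alpha).mean()))
        if planted:
            up = enrich_collection(
                de, coll, method, Direction.UP,
                sig_threshold=sig_threshold, correction=Correction.NONE,
            ).set_index("set_id")["pvalue"]
            down = enrich_collection(
                de, coll, method, Direction.DOWN,
                sig_threshold=sig_threshold, correction=Correction.NONE,
            ).set_index("set_id")["pvalue"]
            for sid, ps in planted.items():
                p_up = float(up.get(sid, 1.0))
                p_down = float(down.get(sid, 1.0))
                if min(p_up, p_down) < alpha:
                    detections[sid] += 1
                    n_detect += 1
                    inferred = Direction.UP if p_up <= p_down else Direction.DOWN
                    if inferred == ps.direction:
                        n_match += 1
    fracs = np.asarray(null_fracs)
    se = float(fracs.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return CalibrationResult(
        type_I_rate=float(fracs.mean()),
        type_I_se=se,
        power={sid: detections[sid] / reps for sid in detections},
        direction_recovery=(n_match / n_detect) if n_detect else float("nan"),
        n_detections=n_detect,
        reps=reps,
    )


def write_fixtures(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit map.tsv, ortho.tsv, sets.gmt, de.tsv and a manifest recording
    the configuration and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping = gen_mapping_table(cfg)
    ortho = gen_orthology(cfg)
    universe = zfish_universe(cfg)
    coll = gen_collection(cfg, universe)
    de = gen_de_table(cfg, universe, coll)
    paths = {
        "map": outdir / "map.tsv",
        "ortho": outdir / "ortho.tsv",
        "sets": outdir / "sets.gmt",
        "de": outdir / "de.tsv",
        "manifest": outdir / "manifest.json",
    }
    mapping.write(paths["map"])
    from .idmap import write_orthology

    write_orthology(ortho, paths["ortho"])
    write_gmt(coll, paths["sets"])
    de.frame.to_csv(paths["de"], sep="\t", index=False)
    manifest = asdict(cfg)
    manifest["planted_sets"] = [
        {"set_id": ps.set_id, "effect": ps.effect, "direction": ps.direction.value}
        for ps in cfg.planted_sets
    ]
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return paths
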