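"""Parameter containers and structured config loading.

A parameter set bundles the reaction free-energy barriers, the polymerase
mismatch-discrimination factor, the NTP pool, the bubble geometry, physical
constants and the nearest-neighbor tables. Sets load from a sectioned YAML
file; unknown keys are fatal so that typos never silently fall back to
defaults. Every derived output embeds ``ModelParams.fingerprint()`` so a run
can be replayed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .thermo import BubbleGeometry, NNTableSet, load_default_tables

_RXN_TYPES = ("translocation", "backstep", "ntp_association",
              "ntp_dissociation", "bond_formation", "cleavage")


@dataclass(frozen=True)
class BarrierSet:
    """Fixed free-energy barriers per reaction type, with k_pre, R and T."""

    dG_ddag: dict[str, float]
    k_pre: float = 1.0e6          # 1/s (1/(uM*s) for association)
    T: float = 310.15             # K
    R: float = 1.987e-3           # kcal/(mol*K)

    def __post_init__(self):
        missing = set(_RXN_TYPES) - set(self.dG_ddag)
        if missing:
            raise ValueError(f"missing barrier(s): {sorted(missing)}")
        extra = set(self.dG_ddag) - set(_RXN_TYPES)
        if extra:
            raise ValueError(f"unknown barrier(s): {sorted(extra)}")
        if any(v < 0 for v in self.dG_ddag.values()):
            raise ValueError("all barriers must be >= 0")
        if self.k_pre <= 0 or self.T <= 0 or self.R <= 0:
            raise ValueError("k_pre, T and R must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class PolymeraseEffectConfig:
    factor: float = 50.0
    back_stabilization_ddG: float = 1.0  # kcal/mol

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("polymerase-effect factor must be >= 1")
        if self.back_stabilization_ddG < 0:
            raise ValueError("BACK stabilization must be >= 0")


@dataclass(frozen=True)
class NTPPool:
    """External NTP concentrations in uM, keyed by RNA base."""

    conc: dict[str, float] = field(default_factory=lambda: {
        "A": 3000.0, "C": 500.0, "G": 1000.0, "U": 1000.0})

    def __post_init__(self):
        if set(self.conc) != set("ACGU") or any(v <= 0 for v in self.conc.values()):
            raise ValueError("NTP pool needs positive concentrations for A, C, G, U")

    def __getitem__(self, base: str) -> float:
        return self.conc[base]

    def noncognate_sum(self, cognate: str) -> float:
        return sum(v for b, v in self.conc.items() if b != cognate)


@dataclass
class ModelParams:
    barriers: BarrierSet
    pe: PolymeraseEffectConfig
    pool: NTPPool
    geometry: BubbleGeometry
    tables: NNTableSet
    dG_pol: float = 0.0
    name: str = "default"

    def fingerprint(self) -> str:
        payload = {
            "barriers": dict(sorted(self.barriers.dG_ddag.items())),
            "k_pre": self.barriers.k_pre, "T": self.barriers.T, "R": self.barriers.R,
            "factor": self.pe.factor, "back_ddG": self.pe.back_stabilization_ddG,
            "pool": dict(sorted(self.pool.conc.items())),
            "geometry": [self.geometry.melted_dna_bp, self.geometry.hybrid_bp],
            "dG_pol": self.dG_pol,
            "tables": [sorted(self.tables.dna_dna.entries.items()),
                       sorted(self.tables.rna_dna_wc.entries.items()),
                       sorted(self.tables.rna_dna_mismatch.entries.items())],
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:12]


_SECTIONS = {"constants", "geometry", "barriers", "polymerase_effect",
             "ntp_pool", "dG_pol", "nn_tables", "name"}
_NTP_KEYS = {"ATP": "A", "CTP": "C", "GTP": "G", "UTP": "U"}


def params_from_dict(cfg: dict, tables: NNTableSet | None = None) -> ModelParams:
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    consts = cfg.get("constants", {})
    barriers = BarrierSet(
        dG_ddag={k: float(v) for k, v in cfg["barriers"].items()},
        k_pre=float(consts.get("k_pre", 1.0e6)),
        T=float(consts.get("T", 310.15)),
        R=float(consts.get("R", 1.987e-3)))
    pe_cfg = cfg.get("polymerase_effect", {})
    pe = PolymeraseEffectConfig(
        factor=float(pe_cfg.get("factor", 50.0)),
        back_stabilization_ddG=float(pe_cfg.get("back_stabilization_ddG", 1.0)))
    pool_cfg = cfg.get("ntp_pool", {})
    conc = {_NTP_KEYS.get(k, k): float(v) for k, v in pool_cfg.items()} or None
    pool = NTPPool(conc) if conc else NTPPool()
    geom_cfg = cfg.get("geometry", {})
    geometry = BubbleGeometry(
        melted_dna_bp=int(geom_cfg.get("melted_dna_bp", 12)),
        hybrid_bp=int(geom_cfg.get("hybrid_bp", 9)))
    if tables is None:
        tbl_cfg = cfg.get("nn_tables", {})
        if any(v != "default" for v in tbl_cfg.values()):
            from .thermo import DuplexClass, NNTable
            base = load_default_tables()
            if tbl_cfg.get("dna_dna", "default") != "default":
                base.dna_dna = NNTable.from_tsv(tbl_cfg["dna_dna"], DuplexClass.DNA_DNA)
            if tbl_cfg.get("rna_dna_wc", "default") != "default":
                base.rna_dna_wc = NNTable.from_tsv(tbl_cfg["rna_dna_wc"], DuplexClass.RNA_DNA_WC)
            if tbl_cfg.get("rna_dna_mismatch", "default") != "default":
                base.rna_dna_mismatch = NNTable.from_tsv(
                    tbl_cfg["rna_dna_mismatch"], DuplexClass.RNA_DNA_MISMATCH)
            tables = base
        else:
            tables = load_default_tables()
    return ModelParams(barriers=barriers, pe=pe, pool=pool, geometry=geometry,
                       tables=tables, dG_pol=float(cfg.get("dG_pol", 0.0)),
                       name=str(cfg.get("name", "default")))


def load_params(path: str) -> ModelParams:
    """Load a parameter set from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return params_from_dict(cfg)


def default_params() -> ModelParams:
    """The parameter set shipped with the package."""
    with (resources.files("txfidelity.data") / "default_params.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return params_from_dict(cfg)
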