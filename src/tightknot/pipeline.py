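"""Pipeline orchestration: one reproducible characterization run.

A flat YAML config enables any subset of the five analysis stages
(titration kinetics, envelope deconvolution, sequence physicochemistry,
cysteine-framework classification, interface geometry), points at the
input files, and overrides numeric defaults. The consolidated report is
deterministic for a fixed config and seed: stage failures are isolated
and recorded, provenance carries input digests, and no timestamps are
embedded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import TightknotError, ValidationError
from . import cysframe, contacts, kinetics, massspec, seqprops

STAGES = ("titration", "envelope", "sequence", "cysframe", "contacts")


@dataclass
class RunConfig:
    """Flat run configuration; every numeric default appears here."""

    # stage toggles
    run_titration: bool = False
    run_envelope: bool = False
    run_sequence: bool = False
    run_cysframe: bool = False
    run_contacts: bool = False
    # input paths
    titration_csv: str | None = None
    envelope_csv: str | None = None
    fasta: str | None = None
    peptides_txt: str | None = None
    alignment_fasta: str | None = None
    pdb: str | None = None
    # parameters
    enzyme_total_nM: float | None = 515.0
    kd_method: str = "stoichiometric"
    z_min: int = 1
    z_max: int = 30
    adduct_mass: float = massspec.PROTON_MASS
    envelope_max_rel_spread: float = 0.01
    cleavage: int | None = None
    bonds: str | None = None          # e.g. "1-4,2-5,3-7,6-9,8-10"
    hbond_cutoff: float = 3.5
    interface_cutoff: float = 4.0
    chain_a: str = "A"
    chain_b: str = "B"
    flag_residues: list[int] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def validate(self):
        enabled = self.enabled_stages()
        if not enabled:
            raise ValidationError("config: at least one stage must be enabled")
        requirements = {
            "titration": [self.titration_csv],
            "envelope": [self.envelope_csv],
            "sequence": [self.fasta],
            "cysframe": [self.fasta],
            "contacts": [self.pdb, self.fasta],
        }
        for stage in enabled:
            for path in requirements[stage]:
                if path is None:
                    raise ValidationError(f"config: stage {stage!r} needs an input path")
                if not Path(path).exists():
                    raise ValidationError(f"config: input {path!r} does not exist")

    def enabled_stages(self) -> list[str]:
        return [s for s in STAGES if getattr(self, f"run_{s}")]


@dataclass
class CharacterizationReport:
    stages: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"stages": self.stages, "provenance": self.provenance},
                          indent=indent, sort_keys=True)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (frozenset, set, tuple)):
        return [_jsonable(x) for x in sorted(obj, key=repr)]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(x) for x in obj]
    return obj


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage_titration(cfg: RunConfig) -> dict:
    series = kinetics.TitrationSeries.from_csv(cfg.titration_csv, cfg.enzyme_total_nM)
    model = kinetics.TightBindingTitration(series, cfg.enzyme_total_nM)
    est = model.fit(method=cfg.kd_method, seed=cfg.seed) \
        if cfg.kd_method == "stoichiometric" else model.fit(method=cfg.kd_method)
    return _jsonable(est)


def _stage_envelope(cfg: RunConfig) -> dict:
    env = massspec.IonEnvelope.from_csv(cfg.envelope_csv)
    res = massspec.deconvolve(env, cfg.z_min, cfg.z_max, cfg.adduct_mass,
                              max_rel_spread=cfg.envelope_max_rel_spread)
    return _jsonable(res)


def _load_first_seq(cfg: RunConfig) -> seqprops.ProteinSequence:
    seq = seqprops.read_fasta(cfg.fasta)[0]
    if cfg.cleavage:
        seq = seqprops.ProteinSequence(seq.id, seq.residues, cleavage=cfg.cleavage)
    return seq


def _stage_sequence(cfg: RunConfig) -> dict:
    seq = _load_first_seq(cfg)
    out = {"id": seq.id, "profile": _jsonable(seqprops.physchem_profile(seq)),
           "pest": [_jsonable(m) for m in seqprops.find_pest(seq)]}
    if seq.cleavage:
        mature = seqprops.mature_sequence(seq)
        out["mature"] = {"id": mature.id,
                         "profile": _jsonable(seqprops.physchem_profile(mature))}
    if cfg.peptides_txt:
        peptides = [l.strip() for l in Path(cfg.peptides_txt).read_text().split()
                    if l.strip()]
        out["coverage_percent"] = seqprops.sequence_coverage(peptides, seq)
    return out


def _stage_cysframe(cfg: RunConfig) -> dict:
    seq = _load_first_seq(cfg)
    fw = cysframe.extract_framework(seq)
    out = {"framework": _jsonable(fw),
           "candidates": [t.name for t in cysframe.candidate_families(fw)]}
    if cfg.bonds:
        pattern = cysframe.ConnectivityPattern.from_string(cfg.bonds)
        out["family_match"] = _jsonable(cysframe.classify_connectivity(pattern))
    if cfg.alignment_fasta:
        aln = [s.residues for s in seqprops.read_fasta(cfg.alignment_fasta)]
        out["conserved_cys_columns"] = cysframe.conserved_cys_columns(aln)
    return out


def _stage_contacts(cfg: RunConfig) -> dict:
    model = contacts.parse_structure(Path(cfg.pdb).read_text())
    hbonds = contacts.find_hbonds(model, cfg.chain_a, cfg.chain_b, cfg.hbond_cutoff)
    report = contacts.interface_residues(model, cfg.chain_a, cfg.chain_b,
                                         cfg.interface_cutoff,
                                         cfg.flag_residues or None)
    seq = _load_first_seq(cfg)
    loops = contacts.reactive_loop_candidates(seq)
    return {"hydrogen_bonds": [_jsonable(h) for h in hbonds],
            "interface": _jsonable(report),
            "reactive_loops": [_jsonable(l) for l in loops]}


_STAGE_FUNCS = {"titration": _stage_titration, "envelope": _stage_envelope,
                "sequence": _stage_sequence, "cysframe": _stage_cysframe,
                "contacts": _stage_contacts}


def run(config: RunConfig) -> CharacterizationReport:
    """Execute the enabled stages; failures are isolated per stage."""
    config.validate()
    stages = {}
    for name in config.enabled_stages():
        try:
            stages[name] = _STAGE_FUNCS[name](config)
        except TightknotError as exc:
            stages[name] = {"error": f"{type(exc).__name__}: {exc}"}
    cfg_dict = dataclasses.asdict(config)
    inputs = {k: _digest(v) for k, v in cfg_dict.items()
              if k in ("titration_csv", "envelope_csv", "fasta", "peptides_txt",
                       "alignment_fasta", "pdb") and v and Path(v).exists()}
    provenance = {
        "tightknot_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "input_sha256": inputs,
        "seed": config.seed,
    }
    return CharacterizationReport(stages=stages, provenance=provenance)
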