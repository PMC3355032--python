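"""File formats and pipeline configuration.

CP locus file dialect
---------------------
A plain-text representation of cross-pollinator marker calls::

    name = <population name>
    popt = CP
    nloc = <number of markers>
    nind = <number of individuals>
    individuals = <id> <id> ...

    <marker> <{code}> {<phase>} <token> <token> ...

with one marker per line after a single blank separator line.  ``code`` is
one of lmxll, nnxnp, hkxhk, efxeg, abxcd written in angle brackets; the
phase field is brace-delimited and defaults to ``{--}``; tokens are the
code's genotype classes (e.g. ``ll``/``lm`` for <lmxll>) or ``--`` for
missing, one per individual in header order, separated by single spaces.
Files written here round-trip byte-identically through the reader.

All tabular outputs are TSV with '.' decimal separators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calling import CP_TOKENS, CPCall, MISSING
from .errors import ParseError


def write_cp_locus_file(path, calls: dict[str, CPCall],
                        individuals: list[str], name: str = "population"):
    lines = [
        f"name = {name}",
        "popt = CP",
        f"nloc = {len(calls)}",
        f"nind = {len(individuals)}",
        "individuals = " + " ".join(individuals),
        "",
    ]
    for marker_id in sorted(calls):
        c = calls[marker_id]
        tokens = " ".join(c.tokens(individuals))
        lines.append(f"{marker_id} <{c.cp_code}> {{{c.phase}}} {tokens}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cp_locus_file(path) -> tuple[dict[str, CPCall], list[str], str]:
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    individuals: list[str] = []
    calls: dict[str, CPCall] = {}
    name = "population"
    for lineno, raw in enumerate(text, start=1):
        line = raw.rstrip()
        if not line or line.startswith(";"):
            continue
        if "=" in line and not calls and not line.startswith(tuple(CP_TOKENS)):
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "individuals":
                individuals = value.split()
            else:
                header[key] = value
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"malformed marker line: {raw!r}", lineno)
        marker_id, code_field, phase_field = parts[0], parts[1], parts[2]
        if not (code_field.startswith("<") and code_field.endswith(">")):
            raise ParseError(f"segregation code must be angle-bracketed, got "
                             f"{code_field!r}", lineno)
        code = code_field[1:-1]
        if code not in CP_TOKENS:
            raise ParseError(f"unknown segregation code {code!r}", lineno)
        if not (phase_field.startswith("{") and phase_field.endswith("}")):
            raise ParseError(f"phase field must be brace-delimited, got "
                             f"{phase_field!r}", lineno)
        tokens = parts[3:]
        if len(tokens) != len(individuals):
            raise ParseError(
                f"marker {marker_id}: {len(tokens)} genotype tokens for "
                f"{len(individuals)} individuals", lineno)
        valid = set(CP_TOKENS[code]) | {MISSING}
        for t in tokens:
            if t not in valid:
                raise ParseError(
                    f"marker {marker_id}: token {t!r} invalid for code "
                    f"<{code}>", lineno)
        calls[marker_id] = CPCall(
            marker_id, code,
            {i: t for i, t in zip(individuals, tokens) if t != MISSING},
            phase=phase_field[1:-1])
    name = header.get("name", name)
    return calls, individuals, name


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    n_chrom: int = 10
    length_range_cM: tuple[float, float] = (88.0, 100.0)
    centromere_fraction_range: tuple[float, float] = (0.35, 0.65)
    fusion_inserted_lg: str = "7b"
    fusion_target_lg: str = "4b"
    n_snv: int = 500
    n_ssr: int = 60
    n_f1: int = 221
    n_doubled_haploid: int = 2
    gain: float = 1.0
    noise_sd: float = 0.03
    ssr_dropout: float = 0.02
    n_distortion_loci: int = 2
    distortion_weights: tuple[float, ...] = (0.3, 0.65)


@dataclass
class CallingConfig:
    r_floor: float = 0.5
    k_max: int = 5
    min_weight: float = 0.02
    min_sep: float = 0.1
    center_tolerance: float = 0.12
    skew_tolerance: float = 0.08


@dataclass
class MappingConfig:
    lod_min: float = 11.0
    rf_max: float = 0.4
    orphan_cm: float = 40.0
    alpha: float = 0.005
    min_n: int = 20


@dataclass
class SyntenyConfig:
    min_share: float = 0.8
    min_block: int = 4
    min_markers: int = 5
    p_unassignable: float = 0.05
    spurious_rate: float = 0.3


@dataclass
class PipelineConfig:
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list)
            .encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in (sub or {}).items():
                if k not in fields:
                    raise ParseError(f"unknown config key {k!r}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)
        return cls(
            seed=int(d.get("seed", 1)),
            simulation=build(SimulationConfig, d.get("simulation")),
            calling=build(CallingConfig, d.get("calling")),
            mapping=build(MappingConfig, d.get("mapping")),
            synteny=build(SyntenyConfig, d.get("synteny")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)),
                           fh, sort_keys=False)


def read_external_map_table(path, marker_col: str = "marker",
                            lg_col: str = "linkage_group",
                            pos_col: str = "position_cM"):
    """Optional reader for externally published map-position tables.

    Accepts a delimited text table (TSV/CSV sniffed from the extension)
    with one row per mapped marker.  Column names can be remapped to match
    a particular published layout.  Never required by the pipeline; the
    simulator is the default data source.
    """
    import pandas as pd

    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in (marker_col, lg_col, pos_col):
        if col not in df.columns:
            raise ParseError(f"expected column {col!r} in {path}")
    out = df[[marker_col, lg_col, pos_col]].copy()
    out.columns = ["marker_id", "lg", "pos_cM"]
    return out


def read_external_genotype_table(path, marker_col: str = "marker",
                                 code_col: str = "segregation"):
    """Optional reader for externally published genotype-score tables.

    Layout: one row per marker with its CP segregation code and one
    column per individual holding genotype tokens ('--' for missing).
    Returns a dict marker_id -> CPCall.  Never required by the pipeline.
    """
    import pandas as pd

    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (marker_col, code_col):
        if col not in df.columns:
            raise ParseError(f"expected column {col!r} in {path}")
    individuals = [c for c in df.columns if c not in (marker_col, code_col)]
    calls: dict[str, CPCall] = {}
    for _, row in df.iterrows():
        code = row[code_col].strip().strip("<>")
        if code not in CP_TOKENS:
            raise ParseError(f"unknown segregation code {code!r} for marker "
                             f"{row[marker_col]!r}")
        valid = set(CP_TOKENS[code]) | {MISSING}
        geno = {}
        for ind in individuals:
            tok = (row[ind] or MISSING).strip()
            if tok not in valid:
                raise ParseError(f"marker {row[marker_col]}: token {tok!r} "
                                 f"invalid for code <{code}>")
            if tok != MISSING:
                geno[ind] = tok
        calls[row[marker_col]] = CPCall(row[marker_col], code, geno)
    return calls


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False)


def write_map_tsv(gmap, path):
    import pandas as pd

    rows = []
    for g in gmap.groups:
        for m, p in zip(g.markers, g.positions):
            rows.append((m, g.lg_index, round(p, 4), gmap.provenance,
                         gmap.informativeness.get(m, "")))
    write_tsv(pd.DataFrame(rows, columns=[
        "marker_id", "lg", "pos_cM", "provenance", "informative_in"]), path)


def write_pairwise_tsv(table, path):
    import pandas as pd

    rows = [(pl.marker_i, pl.marker_j, round(pl.rf_hat, 5), pl.phase,
             round(pl.lod_independence, 3), pl.n)
            for pl in table.values()]
    write_tsv(pd.DataFrame(rows, columns=[
        "marker_i", "marker_j", "rf_hat", "phase", "lod_independence", "n"]),
        path)
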