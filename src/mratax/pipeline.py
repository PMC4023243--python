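"""End-to-end pipeline: configuration, report assembly, combined verdicts.

A pipeline run joins the morphometric evidence (best-ratio range overlap)
with the molecular evidence (barcoding-gap flags per marker) into one
per-OTU-pair verdict table.  The verdict is a pure function of the
component flags:

===============  ==========  ==========  ============================
morph non-olap   gap mk 1    gap mk 2    verdict
===============  ==========  ==========  ============================
True             any         any         distinct
False            True        True        distinct
False            one of the two only     cryptic-species candidate
False            False       False       not separable
not evaluated    True        True        distinct
not evaluated    one/none                cryptic-species candidate/
                                         not separable
any              not evaluated (both)    follows morphometric flag
===============  ==========  ==========  ============================

Markers or morphometrics absent from the config are marked
"not evaluated" and treated as False in the truth table.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminant import comparison_suite
from .moldist import (
    barcoding_gap_summary,
    code_indels,
    distance_matrix,
    read_alignment,
    read_otu_map,
)
from .morpho import allometry_ratio_spectrum, pca_ratio_spectrum, shape_pca
from .tables import MeasurementTable, read_measurements

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_DEGENERATE = 3

FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``alignments`` maps marker name -> FASTA path; ``otu_maps`` optionally
    maps marker name -> 2-column TSV path.  ``comparisons`` lists
    (sex, group_1, group_2-or-"rest") triples.  A seed is mandatory because
    the ratio-spectrum bootstrap is stochastic.
    """

    out_dir: Path
    seed: int
    measurements: Path | None = None
    alignments: dict[str, Path] = field(default_factory=dict)
    otu_maps: dict[str, Path] = field(default_factory=dict)
    comparisons: tuple[tuple[str, str, str], ...] = ()
    sexes: tuple[str, ...] = ("female", "male")
    n_boot: int = 1000
    model: str = "gtr"
    spectra: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        base = Path(path).parent

        def _resolve(p):
            q = Path(p)
            return q if q.is_absolute() else base / q

        try:
            seed = int(raw["seed"])
        except KeyError:
            raise ConfigError("seed is mandatory") from None
        meas = raw.get("measurements")
        aln = {k: _resolve(v) for k, v in raw.get("alignments", {}).items()}
        maps = {k: _resolve(v) for k, v in raw.get("otu_maps", {}).items()}
        comps = tuple(
            (c["sex"], c["group1"], c.get("group2", "rest"))
            for c in raw.get("comparisons", [])
        )
        cfg = cls(
            out_dir=_resolve(raw.get("out", "mratax_out")),
            seed=seed,
            measurements=_resolve(meas) if meas else None,
            alignments=aln,
            otu_maps=maps,
            comparisons=comps,
            sexes=tuple(raw.get("sexes", ("female", "male"))),
            n_boot=int(raw.get("n_boot", 1000)),
            model=raw.get("model", "gtr"),
            spectra=bool(raw.get("spectra", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.measurements, *self.alignments.values(),
                  *self.otu_maps.values()]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if self.measurements is None and not self.alignments:
            raise ConfigError("nothing to do: no measurements, no alignments")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def verdict(morph_nonoverlap: bool | None, gap_flags: dict[str, bool | None]):
    """Combined species-hypothesis verdict from component flags.

    ``None`` means "not evaluated" and counts as False.  Returns one of
    "distinct", "cryptic-species candidate", "not separable".
    """
    m = bool(morph_nonoverlap)
    gaps = [bool(v) for v in gap_flags.values()]
    evaluated = [v for v in gap_flags.values() if v is not None]
    if m or (len(evaluated) >= 2 and all(bool(v) for v in evaluated)):
        return "distinct"
    if any(gaps):
        return "cryptic-species candidate"
    return "not separable"


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute a full run and write the report bundle to config.out_dir.

    Morpho-only and molecular-only runs are allowed; the absent half is
    marked "not evaluated" in the combined verdict table.  All outputs are
    TSV with fixed column order and explicit float precision, so an
    unchanged config byte-reproduces every file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("mratax %s | seed=%d", __version__, config.seed)
    for p in [config.measurements, *config.alignments.values()]:
        if p is not None:
            logger.info("input %s sha256:%s", p, _digest(Path(p)))

    results: dict[str, pd.DataFrame] = {}
    morph_flags: dict[tuple[str, str], bool] = {}

    # --- morphometrics
    if config.measurements is not None:
        table = read_measurements(config.measurements)
        suite_rows = []
        for si, sex in enumerate(config.sexes):
            sub = table.by_sex(sex)
            if sub.n < 3:
                logger.warning("skipping sex %s: %d specimens", sex, sub.n)
                continue
            decomp = shape_pca(sub)
            _write_tsv(decomp.scores_frame(), out / f"scores_{sex}.tsv")
            if config.spectra:
                spec = pca_ratio_spectrum(
                    sub, pc_index=1, n_boot=config.n_boot,
                    seed=config.seed + si,
                )
                _write_tsv(spec.to_frame(), out / f"pca_spectrum_{sex}.tsv")
                allo = allometry_ratio_spectrum(
                    sub, n_boot=config.n_boot, seed=config.seed + 100 + si,
                )
                _write_tsv(allo.to_frame(),
                           out / f"allometry_spectrum_{sex}.tsv")
            comps = [c for c in config.comparisons if c[0] == sex]
            if comps:
                df = comparison_suite(table, comps)
                suite_rows.append(df)
        if suite_rows:
            suite = pd.concat(suite_rows, ignore_index=True)
            _write_tsv(suite, out / "discriminant_suite.tsv")
            results["discriminant_suite"] = suite
            for _, row in suite.iterrows():
                g1, g2 = row["comparison"].split("-", 1)
                key = tuple(sorted((g1, g2)))
                nonoverlap = not bool(row["overlap_flag"])
                morph_flags[key] = morph_flags.get(key, False) or nonoverlap

    # --- molecular
    gap_flags: dict[str, dict[tuple[str, str], bool]] = {}
    for marker, path in sorted(config.alignments.items()):
        otu_map = (
            read_otu_map(config.otu_maps[marker])
            if marker in config.otu_maps else None
        )
        aln = read_alignment(path, otu_map=otu_map)
        dm = distance_matrix(aln, model=config.model)
        mat = dm.to_frame(percent=True)
        mat.insert(0, "sequence_id", mat.index)
        _write_tsv(mat, out / f"distances_{marker}.tsv")
        gaps = barcoding_gap_summary(dm)
        _write_tsv(gaps, out / f"gap_summary_{marker}.tsv")
        results[f"gap_summary_{marker}"] = gaps
        indels = code_indels(aln)
        if indels.characters:
            (out / f"indels_{marker}.phy").write_text(indels.to_phylip())
            _write_tsv(indels.to_frame(), out / f"indels_{marker}.tsv")
        # pairwise OTU gap flags: within-max of both OTUs < between-min
        flags: dict[tuple[str, str], bool] = {}
        otus = sorted(set(aln.otus))
        labels = np.asarray(aln.otus)
        for i, o1 in enumerate(otus):
            for o2 in otus[i + 1:]:
                idx1 = np.where(labels == o1)[0]
                idx2 = np.where(labels == o2)[0]
                between = float(np.nanmin(dm.d[np.ix_(idx1, idx2)]))
                wmaxes = []
                for idx in (idx1, idx2):
                    if len(idx) > 1:
                        iu = np.triu_indices(len(idx), k=1)
                        wmaxes.append(
                            float(np.nanmax(dm.d[np.ix_(idx, idx)][iu]))
                        )
                    else:
                        wmaxes.append(0.0)
                flags[(o1, o2)] = max(wmaxes) < between
        gap_flags[marker] = flags

    # --- combined verdicts
    pairs = set(morph_flags)
    for flags in gap_flags.values():
        pairs.update(flags)
    if pairs:
        rows = []
        for pair in sorted(pairs):
            morph = morph_flags.get(pair)
            gaps_for_pair = {
                marker: gap_flags[marker].get(pair)
                for marker in sorted(config.alignments)
            }
            row = {
                "otu_pair": "-".join(pair),
                "morph_nonoverlap": (
                    "not evaluated" if morph is None else str(bool(morph))
                ),
            }
            for marker, val in gaps_for_pair.items():
                row[f"gap_{marker}"] = (
                    "not evaluated" if val is None else str(bool(val))
                )
            row["verdict"] = verdict(morph, gaps_for_pair)
            rows.append(row)
        verdicts = pd.DataFrame(rows)
        _write_tsv(verdicts, out / "verdicts.tsv")
        results["verdicts"] = verdicts
    return results


def main_run(config_path: str) -> int:
    """CLI entry: run a pipeline from a TOML config; map errors to exit
    codes (0 ok, 2 validation failure, 3 degenerate computation)."""
    try:
        config = PipelineConfig.from_toml(config_path)
        run_pipeline(config)
    except (ConfigError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return EXIT_VALIDATION
    except FloatingPointError as exc:
        print(f"degenerate computation: {exc}", file=sys.stderr)
        return EXIT_DEGENERATE
    return EXIT_OK
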