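"""Bidirectional signatures: load, write, validate, filter, construct.

A bidirectional signature is a named pair of gene lists: genes expected
to go UP when the pathway/regulator is active ("activated") and genes
expected to go DOWN ("inhibited").  Two on-disk dialects are supported:

* a native long format, tab-delimited::

      name<TAB>UP|DOWN<TAB>comma-separated gene symbols

  with ``#`` comment lines allowed, and

* GMT (``name<TAB>description<TAB>gene...``) where signatures are
  reconstructed by pairing sets whose names differ only by a recognized
  up/down suffix or phrase (``_UP``/``_DN``, ``_UP``/``_DOWN``,
  ``positive regulation``/``negative regulation``).

Gene symbols are upper-cased on load so matching is case-insensitive.
A gene appearing on both sides of one signature is removed from both
(the two lists must form independent populations) and a warning is
logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BidirectionalSignature",
    "SignatureError",
    "SignatureParseError",
    "load_signature_file",
    "write_signature_file",
    "pair_gmt_sets",
    "filter_signatures",
    "read_differential_table",
    "tidy_differential",
    "build_signature_from_differential",
    "build_consensus_signature",
]


class SignatureError(ValueError):
    """Invalid signature content (empty side, bad thresholds, ...)."""


class SignatureParseError(SignatureError):
    """Malformed signature file; message carries the line number."""


def _canonical_genes(genes: Iterable[str]) -> tuple[str, ...]:
    """Upper-case, strip, and de-duplicate preserving first occurrence."""
    seen: dict[str, None] = {}
    for g in genes:
        g = str(g).strip().upper()
        if g:
            seen.setdefault(g, None)
    return tuple(seen)


@dataclass(frozen=True)
class BidirectionalSignature:
    """A named pair of disjoint gene lists: activated ("up") and inhibited ("down")."""

    name: str
    activated: tuple[str, ...]
    inhibited: tuple[str, ...]

    @classmethod
    def from_gene_lists(
        cls,
        name: str,
        activated: Iterable[str],
        inhibited: Iterable[str],
    ) -> "BidirectionalSignature":
        """Build a validated signature.

        Symbols are canonicalized to upper case and de-duplicated; genes
        present on both sides are dropped from both with a warning.
        Raises :class:`SignatureError` if either side ends up empty.
        """
        act = _canonical_genes(activated)
        inh = _canonical_genes(inhibited)
        overlap = set(act) & set(inh)
        if overlap:
            logger.warning(
                "signature %r: %d gene(s) on both sides removed from both: %s",
                name,
                len(overlap),
                ", ".join(sorted(overlap)),
            )
            act = tuple(g for g in act if g not in overlap)
            inh = tuple(g for g in inh if g not in overlap)
        if not act or not inh:
            raise SignatureError(
                f"signature {name!r} needs non-empty activated and inhibited "
                f"lists (got {len(act)} activated, {len(inh)} inhibited)"
            )
        return cls(name=str(name), activated=act, inhibited=inh)

    @property
    def n_activated(self) -> int:
        return len(self.activated)

    @property
    def n_inhibited(self) -> int:
        return len(self.inhibited)

    def __repr__(self) -> str:  # compact: gene lists can be long
        return (
            f"BidirectionalSignature({self.name!r}, "
            f"{self.n_activated} up / {self.n_inhibited} down)"
        )


# --------------------------------------------------------------------------
# file I/O

def load_signature_file(path: str | Path, format: str = "native") -> list[BidirectionalSignature]:
    """Read bidirectional signatures from *path*.

    ``format="native"`` reads the long UP/DOWN dialect; ``format="gmt"``
    reads a GMT file and pairs ``*_UP``/``*_DN`` style sets via
    :func:`pair_gmt_sets` (unpaired sets are logged and dropped).
    """
    path = Path(path)
    if format == "native":
        sigs = _load_native(path)
    elif format == "gmt":
        sets = _load_gmt_sets(path)
        sigs, unpaired = pair_gmt_sets(sets)
        for name, _ in unpaired:
            logger.warning("%s: gene set %r has no up/down partner; dropped", path, name)
    else:
        raise ValueError(f"unknown signature format {format!r}")
    if not sigs:
        raise SignatureParseError(f"{path}: no signatures could be loaded")
    return sigs


def _load_native(path: Path) -> list[BidirectionalSignature]:
    sides: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SignatureParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    f"(name, UP|DOWN, genes), got {len(parts)}"
                )
            name, side, genes = parts
            side = side.strip().upper()
            if side not in ("UP", "DOWN"):
                raise SignatureParseError(
                    f"{path}:{lineno}: second column must be UP or DOWN, got {side!r}"
                )
            entry = sides.setdefault(name, {"UP": [], "DOWN": []})
            if name not in order:
                order.append(name)
            entry[side].extend(genes.split(","))
    sigs = []
    for name in order:
        entry = sides[name]
        if not entry["UP"] or not entry["DOWN"]:
            logger.warning("%s: signature %r lacks an UP or DOWN line; dropped", path, name)
            continue
        sigs.append(BidirectionalSignature.from_gene_lists(name, entry["UP"], entry["DOWN"]))
    return sigs


def _load_gmt_sets(path: Path) -> list[tuple[str, list[str]]]:
    sets: list[tuple[str, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SignatureParseError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    f"at least one gene ({len(parts)} column(s) found)"
                )
            name, _description, *genes = parts
            sets.append((name, [g for g in genes if g.strip()]))
    return sets


def write_signature_file(
    sigs: Sequence[BidirectionalSignature],
    path: str | Path,
    format: str = "native",
) -> None:
    """Write signatures in the native long format or as paired GMT sets."""
    path = Path(path)
    lines: list[str] = []
    if format == "native":
        for s in sigs:
            lines.append(f"{s.name}\tUP\t{','.join(s.activated)}")
            lines.append(f"{s.name}\tDOWN\t{','.join(s.inhibited)}")
    elif format == "gmt":
        for s in sigs:
            lines.append(f"{s.name}_UP\tna\t" + "\t".join(s.activated))
            lines.append(f"{s.name}_DN\tna\t" + "\t".join(s.inhibited))
    else:
        raise ValueError(f"unknown signature format {format!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# recognized (up, down) name markers; matched case-insensitively.
_SUFFIX_PAIRS: tuple[tuple[str, str], ...] = (
    ("_UP", "_DN"),
    ("_UP", "_DOWN"),
)
_PHRASE_PAIR = ("positive regulation", "negative regulation")


def pair_gmt_sets(
    sets: Sequence[tuple[str, Sequence[str]]],
) -> tuple[list[BidirectionalSignature], list[tuple[str, list[str]]]]:
    """Pair plain gene sets into bidirectional signatures by name.

    Sets whose names differ only by ``_UP``/``_DN``, ``_UP``/``_DOWN``
    (suffixes) or the phrases ``positive regulation``/``negative
    regulation`` are merged: the shared base becomes the signature name,
    the "up" set the activated list and the "down" set the inhibited
    list.  Returns ``(signatures, unpaired_sets)``.
    """
    def _keys(name: str) -> list[tuple[str, str, str]]:
        """(normalized base, pairing scheme, direction) keys a set name can play."""
        keys = []
        lower = name.lower()
        for up_suf, dn_suf in _SUFFIX_PAIRS:
            scheme = up_suf + "|" + dn_suf
            if lower.endswith(up_suf.lower()):
                keys.append((lower[: -len(up_suf)], scheme, "up"))
            if lower.endswith(dn_suf.lower()):
                keys.append((lower[: -len(dn_suf)], scheme, "down"))
        if _PHRASE_PAIR[0] in lower:
            keys.append((lower.replace(_PHRASE_PAIR[0], "", 1).strip(), "phrase", "up"))
        if _PHRASE_PAIR[1] in lower:
            keys.append((lower.replace(_PHRASE_PAIR[1], "", 1).strip(), "phrase", "down"))
        return keys

    by_key: dict[tuple[str, str], dict[str, int]] = {}
    for i, (name, _genes) in enumerate(sets):
        for base, scheme, direction in _keys(name):
            by_key.setdefault((base, scheme), {}).setdefault(direction, i)

    sigs: list[BidirectionalSignature] = []
    used: set[int] = set()
    for i, (name, _genes) in enumerate(sets):  # input order drives output order
        if i in used:
            continue
        for base, scheme, direction in _keys(name):
            members = by_key[(base, scheme)]
            if "up" not in members or "down" not in members:
                continue
            i_up, i_dn = members["up"], members["down"]
            if i_up == i_dn or i_up in used or i_dn in used:
                continue
            up_name = sets[i_up][0]
            if scheme == "phrase":
                # "positive regulation of X" -> "regulation of X"
                sig_name = re.sub(
                    re.escape(_PHRASE_PAIR[0]), "regulation", up_name, count=1, flags=re.I
                ).strip()
            else:
                up_suf = scheme.split("|")[0]
                sig_name = up_name[: -len(up_suf)].strip("_") or up_name
            sigs.append(
                BidirectionalSignature.from_gene_lists(
                    sig_name, sets[i_up][1], sets[i_dn][1]
                )
            )
            used.update((i_up, i_dn))
            break
    unpaired = [(name, list(genes)) for i, (name, genes) in enumerate(sets) if i not in used]
    return sigs, unpaired


def filter_signatures(
    sigs: Sequence[BidirectionalSignature],
    min_activated: int = 10,
    min_inhibited: int = 10,
) -> list[BidirectionalSignature]:
    """Keep signatures with at least *min_activated* up and *min_inhibited* down genes.

    The defaults implement the usual curation rule of requiring at least
    10 positively and 10 negatively regulated genes.  Order preserved.
    """
    if min_activated < 1 or min_inhibited < 1:
        raise ValueError("minimum list sizes must be >= 1")
    return [
        s
        for s in sigs
        if s.n_activated >= min_activated and s.n_inhibited >= min_inhibited
    ]


# --------------------------------------------------------------------------
# signature construction from differential-expression tables

def read_differential_table(
    path: str | Path,
    gene_col: str = "gene",
    fc_col: str = "fold_change",
    p_col: str = "p_value",
    fdr_col: str | None = "fdr",
) -> pd.DataFrame:
    """Read a tab-delimited differential-expression table.

    Returns a tidy frame with columns ``gene``, ``fold_change``,
    ``p_value`` and (when present) ``fdr``; see :func:`tidy_differential`
    for the normalization applied.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {gene_col: "gene", fc_col: "fold_change", p_col: "p_value"}
    if fdr_col is not None and fdr_col in df.columns:
        rename[fdr_col] = "fdr"
    missing = [c for c in (gene_col, fc_col, p_col) if c not in df.columns]
    if missing:
        raise SignatureParseError(f"{path}: missing required column(s): {missing}")
    return tidy_differential(df.rename(columns=rename))


def tidy_differential(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a differential table to one row per gene, signed fold-changes.

    Two fold-change dialects are accepted: signed linear fold-changes
    (down-regulation negative) and pure ratios (down-regulation in
    (0, 1)).  If any value lies in (0, 1) and none is negative the column
    is treated as ratios and converted to the signed convention
    (x < 1 becomes -1/x).  Duplicate gene rows keep the smallest p-value
    (probe collapse favoring the strongest probe).
    """
    df = df.copy()
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    fc = pd.to_numeric(df["fold_change"], errors="coerce")
    if not np.isfinite(fc).all() or (fc == 0).any():
        raise SignatureError("fold-change values must be finite and nonzero")
    if ((fc > 0) & (fc < 1)).any() and not (fc < 0).any():
        # ratio dialect: convert to signed linear fold-change
        fc = fc.where(fc >= 1, -1.0 / fc)
    df["fold_change"] = fc
    df = df.sort_values("p_value", kind="mergesort").drop_duplicates("gene", keep="first")
    return df.sort_index().reset_index(drop=True)


def build_signature_from_differential(
    table: pd.DataFrame,
    name: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> BidirectionalSignature:
    """Derive a signature from one differential-expression table.

    Activated genes satisfy ``fold_change > fc_threshold`` and
    ``fdr < fdr_threshold``; inhibited genes satisfy
    ``fold_change < -fc_threshold`` and ``fdr < fdr_threshold``
    (strict inequalities; defaults |FC| > 2, FDR < 0.05).
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if "fdr" not in table.columns:
        raise SignatureError("differential table needs an 'fdr' column")
    t = tidy_differential(table)
    sig_rows = t[t["fdr"] < fdr_threshold]
    up = sig_rows.loc[sig_rows["fold_change"] > fc_threshold, "gene"]
    dn = sig_rows.loc[sig_rows["fold_change"] < -fc_threshold, "gene"]
    if up.empty or dn.empty:
        raise SignatureError(
            f"signature {name!r}: no genes pass on the "
            f"{'activated' if up.empty else 'inhibited'} side "
            f"(|FC| > {fc_threshold}, FDR < {fdr_threshold}); "
            "consider relaxing the thresholds"
        )
    return BidirectionalSignature.from_gene_lists(name, up, dn)


def build_consensus_signature(
    tables: Sequence[pd.DataFrame],
    name: str,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> BidirectionalSignature:
    """Derive a consensus signature from several experiments.

    A gene is included only if it shows ``|fold_change| > fc_threshold``
    and ``p_value < p_threshold`` in **every** table, with the same
    fold-change sign in every table.  The shared sign assigns the gene
    to the activated (positive) or inhibited (negative) list.  Defaults
    implement the common consensus rule |FC| > 1.5, p < 0.05.
    """
    if len(tables) < 2:
        raise ValueError("consensus requires at least 2 tables")
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    tidied = [tidy_differential(t) for t in tables]
    up: set[str] | None = None
    dn: set[str] | None = None
    for t in tidied:
        passed = t[(t["fold_change"].abs() > fc_threshold) & (t["p_value"] < p_threshold)]
        t_up = set(passed.loc[passed["fold_change"] > 0, "gene"])
        t_dn = set(passed.loc[passed["fold_change"] < 0, "gene"])
        up = t_up if up is None else up & t_up
        dn = t_dn if dn is None else dn & t_dn
    assert up is not None and dn is not None
    if not up or not dn:
        raise SignatureError(
            f"consensus signature {name!r}: no genes pass in all {len(tables)} "
            f"tables on the {'activated' if not up else 'inhibited'} side; "
            "consider relaxing the thresholds"
        )
    return BidirectionalSignature.from_gene_lists(name, sorted(up), sorted(dn))
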