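"""Adapter for MEME plain-text output.

Parses the "sites sorted by position p-value" block of classic MEME
text reports into :class:`~motifbench.evaluate.PredictionRun` objects so
external MEME runs can be scored with the same evaluation engine.  Only
the site table is read (sequence name, optional strand, 1-based start,
p-value, site string); sequence names are expected to be the FASTA
headers written by this package, ``dataset|species|gene``.
"""

from __future__ import annotations

import re
from pathlib import Path

from .evaluate import PredictedSite, PredictionRun

_SITE_HEADER = re.compile(r"sites sorted by position p-value", re.IGNORECASE)
_DASHES = re.compile(r"^-{3,}")
_ACGT = re.compile(r"^[ACGTacgt]+$")


def parse_meme_text(
    text: str, finder_id: str = "meme", motif_index: int = 1
) -> PredictionRun | None:
    """Parse one motif's site table from MEME plain-text output.

    Returns ``None`` when the requested motif block is absent.  Start
    coordinates are converted from MEME's 1-based to this package's
    0-based half-open convention.
    """
    lines = text.splitlines()
    block_starts = [i for i, ln in enumerate(lines) if _SITE_HEADER.search(ln)]
    if len(block_starts) < motif_index:
        return None
    start_i = block_starts[motif_index - 1]
    sites: list[PredictedSite] = []
    dataset_id = None
    in_table = False
    dash_runs = 0
    for ln in lines[start_i + 1 :]:
        if _DASHES.match(ln.strip()):
            dash_runs += 1
            # the table is delimited by dashed rules; the third closes it
            if in_table and dash_runs >= 3:
                break
            in_table = True
            continue
        if not in_table or not ln.strip():
            continue
        parsed = _parse_site_line(ln)
        if parsed is None:
            continue
        name, strand, start1, site_seq = parsed
        parts = name.split("|")
        if len(parts) != 3:
            continue
        ds, species, gene = parts
        dataset_id = dataset_id or ds
        sites.append(
            PredictedSite(
                species=species, gene=gene,
                start=start1 - 1, end=start1 - 1 + len(site_seq),
                sequence=site_seq.upper(), strand=strand,
            )
        )
    if dataset_id is None:
        return None
    return PredictionRun(dataset_id, finder_id, has_output=True, sites=sites)


def parse_meme_file(path: str | Path, finder_id: str = "meme", motif_index: int = 1):
    return parse_meme_text(Path(path).read_text(), finder_id, motif_index)


def _parse_site_line(ln: str):
    tokens = ln.split()
    if len(tokens) < 4:
        return None
    name = tokens[0]
    rest = tokens[1:]
    strand = "+"
    if rest[0] in ("+", "-"):
        strand = rest[0]
        rest = rest[1:]
    try:
        start1 = int(rest[0])
        float(rest[1])  # p-value
    except (ValueError, IndexError):
        return None
    # remaining tokens: optional left flank, the site, optional right
    # flank (flanks appear only when the site is interior)
    acgt = [t for t in rest[2:] if _ACGT.match(t)]
    if not acgt:
        return None
    if len(acgt) == 3:
        site_seq = acgt[1]
    elif len(acgt) == 1:
        site_seq = acgt[0]
    else:
        site_seq = max(acgt, key=len)
    return name, strand, start1, site_seq
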