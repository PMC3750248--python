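"""Collinear-block detection over two gene orders.

A syntenous block is a maximal run of ortholog pairs whose ordinals
strictly increase in genome A and move monotonically (up = "same", down
= "inverted") in genome B, with at most ``gap_tolerance`` intervening
genes between consecutive pairs on each genome, never spanning a contig
boundary. Blocks are built greedily left to right in A-order with
deterministic tie-breaking, and each ortholog pair lands in at most one
block; equivalence with exhaustive enumeration on small instances is
enforced by the test suite.
"""
from __future__ import annotations

import math
from typing import Sequence

from .model import GenomeRecord, OrthologMap, OrthologPair, SyntenyBlock


def _positions(genome: GenomeRecord, gene_ids, label: str) -> dict[str, tuple[str, int]]:
    pos = genome.gene_positions()
    missing = [g for g in gene_ids if g not in pos]
    if missing:
        raise ValueError(
            f"ortholog gene id {missing[0]!r} not found in genome {label}"
        )
    return pos


def find_synteny_blocks(
    orthomap: OrthologMap,
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    gap_tolerance: int = 1,
    min_block_size: int = 2,
    allow_inversion: bool = True,
) -> list[SyntenyBlock]:
    """Detect maximal collinear runs of ortholog pairs.

    Returns blocks ordered by (contig_a, first A-ordinal). Individual
    gene strands are ignored: collinearity is about gene order, and a
    block's orientation derives from the direction of B-ordinals.
    """
    pos_a = _positions(genome_a, (p.gene_a for p in orthomap.pairs), orthomap.genome_a_id)
    pos_b = _positions(genome_b, (p.gene_b for p in orthomap.pairs), orthomap.genome_b_id)

    # anchors grouped by contig pair, sorted by A-ordinal
    groups: dict[tuple[str, str], list[tuple[int, int, OrthologPair]]] = {}
    for p in orthomap.pairs:
        ca, oa = pos_a[p.gene_a]
        cb, ob = pos_b[p.gene_b]
        groups.setdefault((ca, cb), []).append((oa, ob, p))

    blocks: list[SyntenyBlock] = []
    max_step = gap_tolerance + 1
    for (ca, cb), anchors in groups.items():
        anchors.sort(key=lambda t: t[0])
        used = [False] * len(anchors)
        consumed_seed = [False] * len(anchors)
        for s in range(len(anchors)):
            if used[s] or consumed_seed[s]:
                continue
            chain = [s]
            direction = 0  # 0 undecided, +1 same, -1 inverted
            cur = s
            while True:
                oa, ob, _ = anchors[cur]
                nxt = None
                for j in range(cur + 1, len(anchors)):
                    if used[j] or consumed_seed[j]:
                        continue
                    oa_j, ob_j, _ = anchors[j]
                    if oa_j == oa:
                        continue  # co-located anchors cannot both extend
                    if oa_j - oa > max_step:
                        break  # sorted by A-ordinal: no later anchor can qualify
                    db = ob_j - ob
                    if direction == 0:
                        if 0 < db <= max_step:
                            nxt, new_dir = j, 1
                            break
                        if allow_inversion and 0 < -db <= max_step:
                            nxt, new_dir = j, -1
                            break
                    else:
                        if 0 < db * direction <= max_step:
                            nxt, new_dir = j, direction
                            break
                if nxt is None:
                    break
                direction = new_dir
                chain.append(nxt)
                cur = nxt
            if len(chain) >= min_block_size:
                for j in chain:
                    used[j] = True
                blocks.append(
                    SyntenyBlock(
                        pairs=[anchors[j][2] for j in chain],
                        contig_a=ca,
                        contig_b=cb,
                        orientation="inverted" if direction == -1 else "same",
                    )
                )
            else:
                # release non-seed members for later chains; the seed can
                # never be reached again (extension only moves right in A)
                consumed_seed[s] = True

    first_ordinal = {}
    for b in blocks:
        first_ordinal[id(b)] = pos_a[b.pairs[0].gene_a][1]
    blocks.sort(key=lambda b: (b.contig_a, first_ordinal[id(b)]))
    return blocks


def synteny_metrics(
    blocks: Sequence[SyntenyBlock], orthomap: OrthologMap
) -> tuple[float, float]:
    """(synteny_fraction, mean_block_length).

    The fraction is syntenous ortholog pairs over all ortholog pairs;
    the mean block length is in genes. With no blocks the fraction is
    0.0 and the mean is NaN (undefined).
    """
    n_pairs = len(orthomap.pairs)
    total = sum(b.length for b in blocks)
    if total > n_pairs:
        raise ValueError("blocks contain more pairs than the ortholog map")
    fraction = total / n_pairs if n_pairs else 0.0
    mean_len = total / len(blocks) if blocks else math.nan
    return fraction, mean_len
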