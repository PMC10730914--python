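"""Synteny chaining tests with an exhaustive-subset oracle."""

import itertools
import random

import pytest

from tropanevo.gffio import Gene, GenomeAnnotation
from tropanevo.homology import GeneFamily
from tropanevo.synteny import (Anchor, build_anchors, chain_anchors,
                               depth_ratio, export_dotplot,
                               read_collinearity, write_collinearity)


def mk_anchor(ra, rb, ga=None, gb=None):
    return Anchor(ga or f"a{ra}", gb or f"b{rb}", "c1", "c2", ra, rb, "fam")


def oracle_best_chain(anchors, min_block_size, max_gap,
                      gap_penalty=1.0, match_score=10.0):
    """Max score over every orientation-consistent anchor subset."""
    best = None
    n = len(anchors)
    for r in range(min_block_size, n + 1):
        for combo in itertools.combinations(range(n), r):
            sub = sorted((anchors[i] for i in combo),
                         key=lambda a: (a.rank_a, a.rank_b))
            for sign in (1, -1):
                ok = True
                score = match_score
                genes_a = {sub[0].gene_a}
                genes_b = {sub[0].gene_b}
                for prev, cur in zip(sub, sub[1:]):
                    da = cur.rank_a - prev.rank_a
                    db = sign * (cur.rank_b - prev.rank_b)
                    if da < 1 or db < 1 or da > max_gap or db > max_gap \
                            or cur.gene_a in genes_a or cur.gene_b in genes_b:
                        ok = False
                        break
                    score += match_score - gap_penalty * ((da - 1) + (db - 1))
                    genes_a.add(cur.gene_a)
                    genes_b.add(cur.gene_b)
                if ok:
                    best = score if best is None else max(best, score)
    return best


class TestChaining:
    def test_perfect_collinear_run_is_one_block(self):
        anchors = [mk_anchor(i, i) for i in range(6)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].score == 60.0
        assert blocks[0].orientation == "same"
        assert len(blocks[0].anchors) == 6

    def test_four_anchors_below_minimum_size(self):
        blocks = chain_anchors([mk_anchor(i, i) for i in range(4)])
        assert blocks == []

    def test_reversed_run_is_inverted_block(self):
        anchors = [mk_anchor(i, 9 - i) for i in range(6)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        ranks_b = [a.rank_b for a in blocks[0].anchors]
        assert ranks_b == sorted(ranks_b, reverse=True)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = random.Random(2024)
        checked = 0
        for _ in range(1000):
            n = rng.randint(1, 8)
            max_gap = rng.choice([2, 3, 5, 25])
            min_size = rng.choice([2, 3])
            anchors = []
            seen = set()
            for _ in range(n):
                ra, rb = rng.randint(0, 11), rng.randint(0, 11)
                if (ra, rb) in seen:
                    continue
                seen.add((ra, rb))
                anchors.append(mk_anchor(ra, rb))
            expected = oracle_best_chain(anchors, min_size, max_gap)
            blocks = chain_anchors(anchors, min_block_size=min_size,
                                   max_gap=max_gap)
            got = max((b.score for b in blocks), default=None)
            assert got == expected, (anchors, max_gap, min_size)
            checked += 1
        assert checked >= 900

    def test_blocks_are_anchor_disjoint_subsets_of_input(self):
        rng = random.Random(9)
        anchors = [mk_anchor(ra, rb)
                   for ra, rb in {(rng.randint(0, 30), rng.randint(0, 30))
                                  for _ in range(60)}]
        blocks = chain_anchors(anchors, min_block_size=3)
        seen = set()
        pool = {(a.rank_a, a.rank_b) for a in anchors}
        for b in blocks:
            for a in b.anchors:
                key = (a.rank_a, a.rank_b)
                assert key not in seen
                assert key in pool
                seen.add(key)

    @staticmethod
    def _run_instance(rng):
        """Disjoint collinear runs (some inverted) with clean separations."""
        anchors = []
        ra = rb = 0
        for _ in range(rng.randint(2, 4)):
            length = rng.randint(5, 8)
            inverted = rng.random() < 0.5
            start_b = rb + (length if inverted else 0)
            for k in range(length):
                anchors.append(mk_anchor(
                    ra + k, start_b + (-k if inverted else k),
                    ga=f"a{ra + k}", gb=f"b{rb + k}"))
            ra += length + rng.randint(3, 6)
            rb += length + rng.randint(3, 6)
        return anchors, ra, rb

    def test_invariant_under_joint_order_reversal(self):
        rng = random.Random(17)
        for _ in range(20):
            anchors, na, nb = self._run_instance(rng)
            blocks = chain_anchors(anchors, min_block_size=3)
            flipped = [mk_anchor(na - a.rank_a, nb - a.rank_b,
                                 a.gene_a, a.gene_b) for a in anchors]
            blocks2 = chain_anchors(flipped, min_block_size=3)
            assert sorted((len(b.anchors), b.score, b.orientation)
                          for b in blocks) == \
                sorted((len(b.anchors), b.score, b.orientation)
                       for b in blocks2)

    def test_invariant_under_chromosome_relabeling(self):
        rng = random.Random(23)
        anchors, _, _ = self._run_instance(rng)
        relabeled = [Anchor(a.gene_a, a.gene_b, "chrX", "chrY",
                            a.rank_a, a.rank_b, a.family_id)
                     for a in anchors]
        b1 = chain_anchors(anchors, min_block_size=3)
        b2 = chain_anchors(relabeled, min_block_size=3)
        assert [(len(b.anchors), b.score, b.orientation) for b in b1] == \
            [(len(b.anchors), b.score, b.orientation) for b in b2]


def _toy_genome(species, chrom_genes):
    """chrom_genes: {chrom: [gene ids in order]}"""
    ann = GenomeAnnotation(species=species)
    for chrom, gids in chrom_genes.items():
        for i, gid in enumerate(gids):
            ann.add(Gene(gene_id=gid, chrom=chrom, start=i * 1000,
                         end=i * 1000 + 500))
    return ann


class TestAnchors:
    def test_identical_single_copy_genomes_give_diagonal(self):
        ga = _toy_genome("A", {"c1": [f"A{i}" for i in range(10)]})
        gb = _toy_genome("B", {"c1": [f"B{i}" for i in range(10)]})
        fams = [GeneFamily(f"f{i}", frozenset({f"A{i}", f"B{i}"}))
                for i in range(10)]
        anchors = build_anchors(ga, gb, fams)
        assert len(anchors) == 10
        assert all(a.rank_a == a.rank_b for a in anchors)

    def test_copy_cap_suppresses_repeat_families(self):
        ga = _toy_genome("A", {"c1": [f"A{i}" for i in range(25)]})
        gb = _toy_genome("B", {"c1": ["B0"]})
        fams = [GeneFamily("f", frozenset({f"A{i}" for i in range(25)}
                                          | {"B0"}))]
        assert build_anchors(ga, gb, fams, copy_cap=20) == []
        assert len(build_anchors(ga, gb, fams, copy_cap=30)) == 25

    def test_post_wgd_genome_gives_two_anchors_per_query_gene(self):
        from conftest import SMALL_TREE, small_config
        from tropanevo.simulate import WgdSpec, generate_dataset
        res = generate_dataset(
            SMALL_TREE,
            small_config(seed=8, wgd_branches={"AB": WgdSpec(retention=1.0)}))
        by_fam = {}
        for sp in ("Aaa", "Ccc"):
            for gid, g in res.annotations[sp].genes.items():
                by_fam.setdefault(g.family_truth, set()).add(gid)
        fams = [GeneFamily(sorted(m)[0], frozenset(m))
                for m in by_fam.values()]
        anchors = build_anchors(res.annotations["Ccc"],
                                res.annotations["Aaa"], fams)
        per_query = {}
        for a in anchors:
            per_query[a.gene_a] = per_query.get(a.gene_a, 0) + 1
        assert set(per_query.values()) == {2}
        assert len(per_query) == len(res.annotations["Ccc"].genes)


class TestDepthRatio:
    def _families(self, *groups):
        return [GeneFamily(sorted(g)[0], frozenset(g)) for g in groups]

    def test_identical_genomes_are_one_to_one(self):
        ga = _toy_genome("A", {"c1": [f"A{i}" for i in range(8)]})
        gb = _toy_genome("B", {"c1": [f"B{i}" for i in range(8)]})
        fams = self._families(*({f"A{i}", f"B{i}"} for i in range(8)))
        blocks = chain_anchors(build_anchors(gb, ga, fams),
                               species_a="B", species_b="A")
        profile = depth_ratio(blocks, ga, gb)
        assert profile.modal_ratio == "1:1"

    def test_duplicated_genome_covers_target_twice(self):
        ga = _toy_genome("A", {"c1": [f"A{i}" for i in range(8)]})
        gb = _toy_genome("B", {"c1": [f"B{i}" for i in range(8)],
                               "c2": [f"B{i}x" for i in range(8)]})
        fams = self._families(*({f"A{i}", f"B{i}", f"B{i}x"}
                                for i in range(8)))
        blocks = chain_anchors(build_anchors(gb, ga, fams),
                               species_a="B", species_b="A")
        profile = depth_ratio(blocks, ga, gb)
        assert profile.modal_ratio == "2:1"

    def test_triplication_plus_duplication_covers_reference_sixfold(self):
        """A leaf carrying a triplication and a later duplication (both fully
        retained) covers a pre-polyploidy outgroup 6:1 - the 3x2 structure of
        an ancient triplication with a lineage-specific WGD on top."""
        from conftest import small_config
        from tropanevo.simulate import WgdSpec, generate_dataset
        res = generate_dataset(
            "(Out:20,(Aaa:10,Bbb:10)AB:10)R;",
            small_config(seed=13, n_background_genes_per_chrom=25,
                         wgd_branches={
                             "AB": WgdSpec(retention=1.0, multiplier=3),
                             "Aaa": WgdSpec(retention=1.0, multiplier=2),
                         }))
        by_fam = {}
        for sp in ("Out", "Aaa"):
            for gid, g in res.annotations[sp].genes.items():
                by_fam.setdefault(g.family_truth, set()).add(gid)
        fams = [GeneFamily(sorted(m)[0], frozenset(m))
                for m in by_fam.values()]
        anchors = build_anchors(res.annotations["Aaa"],
                                res.annotations["Out"], fams)
        blocks = chain_anchors(anchors, species_a="Aaa", species_b="Out")
        profile = depth_ratio(blocks, res.annotations["Out"],
                              res.annotations["Aaa"])
        assert profile.modal_ratio == "6:1"

    def test_no_blocks_warns_zero_ratio(self):
        ga = _toy_genome("A", {"c1": ["A0"]})
        gb = _toy_genome("B", {"c1": ["B0"]})
        with pytest.warns(UserWarning):
            profile = depth_ratio([], ga, gb)
        assert profile.modal_ratio == "0:0"


class TestSerialization:
    def test_dotplot_rows_and_roundtrip(self, tmp_path):
        anchors = [mk_anchor(i, i) for i in range(6)]
        blocks = chain_anchors(anchors)
        path = tmp_path / "dots.tsv"
        export_dotplot(blocks, path)
        rows = path.read_text().splitlines()
        assert len(rows) == 7  # header + 6 anchors
        export_dotplot([], tmp_path / "empty.tsv")
        assert (tmp_path / "empty.tsv").read_text().splitlines() == \
            ["rank_a\trank_b\tblock_id\torientation"]

    def test_collinearity_roundtrip(self, tmp_path):
        rng = random.Random(5)
        anchors = [mk_anchor(ra, rb)
                   for ra, rb in {(rng.randint(0, 30), rng.randint(0, 30))
                                  for _ in range(40)}]
        blocks = chain_anchors(anchors, min_block_size=3)
        path = tmp_path / "blocks.txt"
        write_collinearity(blocks, path)
        back = read_collinearity(path)
        assert len(back) == len(blocks)
        for b1, b2 in zip(blocks, back):
            assert b1.block_id == b2.block_id
            assert b1.orientation == b2.orientation
            assert b1.score == b2.score
            assert [(a.gene_a, a.gene_b, a.rank_a, a.rank_b)
                    for a in b1.anchors] == \
                   [(a.gene_a, a.gene_b, a.rank_a, a.rank_b)
                    for a in b2.anchors]
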