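import numpy as np
import pytest

from codechron.dipeptides import SequenceRecord
from codechron.structure import (
    EXCHANGE_GROUPS,
    OMEGA,
    classify_regions,
    dipeptide_class,
    exchange_group_analysis,
    mann_whitney,
    parse_dssp,
    region_bias_test,
    t_omega_ratio,
    write_simple_annotation,
)

CLASSIC_DSSP = """\
==== Secondary Structure Definition by the program DSSP ====
REFERENCE ...
HEADER    SYNTHETIC PROTEIN
  4  1  2  2  0.0
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC
    1    1 A M  H X S+     0   0    0
    2    2 A K  H X S+     0   0    0
    3    3 A L  E     -    0   0    0
    4    4 A G               0   0    0
"""


class TestParsing:
    def test_classic_layout_structure_column(self, tmp_path):
        path = tmp_path / "x.dssp"
        path.write_text(CLASSIC_DSSP)
        chains = parse_dssp(path)
        assert chains == {"A": "HHE "}

    def test_blank_column_is_loop(self, tmp_path):
        path = tmp_path / "x.dssp"
        path.write_text(CLASSIC_DSSP)
        assert parse_dssp(path)["A"][3] == " "

    def test_malformed_header_raises(self, tmp_path):
        path = tmp_path / "x.dssp"
        path.write_text("==== DSSP ====\nno header here\n")
        with pytest.raises(ValueError, match="header"):
            parse_dssp(path)

    def test_simplified_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        structures = {"s1": "HHHEE TTS", "s2": "  GGI BB "}
        write_simple_annotation(structures, path)
        assert parse_dssp(path) == structures


class TestRegionClassification:
    def test_mapping_table(self):
        assert classify_regions("HGIEBTS ") == "HHHEETT" + OMEGA

    def test_all_blank_is_loop(self):
        assert classify_regions("    ") == OMEGA * 4

    def test_length_preserved_and_total(self):
        s = "HGIEBTS HGIEBTS "
        assert len(classify_regions(s)) == len(s)

    def test_unknown_letter_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            classify_regions("HH?")

    def test_boundary_classes_are_symmetric(self):
        assert dipeptide_class("T", OMEGA) == dipeptide_class(OMEGA, "T")


class TestMannWhitney:
    def test_exact_small_sample(self):
        """Fully separated samples of three: U = 0 and one-sided p = 1/20."""
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(0.05)

    def test_exact_matches_enumeration(self):
        """Exact p equals direct enumeration over all label assignments."""
        import itertools

        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        u_obs, p = mann_whitney(x, y, alternative="two-sided")
        pooled = x + y
        n = len(x)
        count = total = 0
        u_values = []
        for combo in itertools.combinations(range(6), n):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for a in xs for b in ys if a > b)
            u_values.append(u)
            total += 1
        mean_u = np.mean(u_values)
        tail = sum(1 for u in u_values
                   if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9)
        assert p == pytest.approx(tail / total)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)


class TestRegionBias:
    def _planted_records(self):
        """Enriched dipeptides confined to helices; loops hold other pairs."""
        rng = np.random.default_rng(0)
        records = []
        for i in range(10):
            n_helix = 10 + int(rng.integers(0, 4)) * 2
            n_loop = 8 + int(rng.integers(0, 4)) * 2
            residues = "AL" * (n_helix // 2) + "GS" * (n_loop // 2)
            structure = "H" * n_helix + " " * n_loop
            records.append(SequenceRecord(f"r{i}", residues, structure=structure))
        return records

    def test_planted_loop_avoidance_flagged(self):
        results = region_bias_test(["AL", "LA"], self._planted_records())
        by_class = {r.dipeptide_class: r for r in results}
        assert by_class[OMEGA].p < 0.05
        assert by_class[OMEGA].direction == "-"
        assert by_class["H"].direction == "+"

    def test_enriched_equals_all_no_signal(self):
        from codechron.dipeptides import DIPEPTIDES

        results = region_bias_test(list(DIPEPTIDES), self._planted_records())
        for r in results:
            assert r.p == pytest.approx(1.0)
            assert r.direction == ""

    def test_requires_structures(self):
        with pytest.raises(ValueError):
            region_bias_test(["AL"], [SequenceRecord("x", "ALAL")])


class TestTOmegaRatio:
    def test_worked_ratio(self):
        # enriched occurrences: 2 at T/loop boundaries, 4 loop-internal
        residues = "ALA" + "LALAL" + "ALAL"
        #            T-O boundary at 2-3?  construct explicitly below
        structure = "TT " + "     " + "T   "
        # positions: AL pairs everywhere; classes: T T O O O O O O T O O O
        rec = SequenceRecord("r", residues, structure=structure)
        res = t_omega_ratio(rec, ["AL", "LA"])
        regions = classify_regions(structure)
        boundary = sum(
            1 for i in range(len(residues) - 1)
            if {regions[i], regions[i + 1]} == {"T", OMEGA}
        )
        other = sum(
            1 for i in range(len(residues) - 1)
            if OMEGA in {regions[i], regions[i + 1]}
            and {regions[i], regions[i + 1]} != {"T", OMEGA}
        )
        assert res.defined
        assert res.n_boundary == boundary
        assert res.n_other_loop == other
        assert res.r == pytest.approx(boundary / other)

    def test_no_loop_dipeptides_undefined(self):
        rec = SequenceRecord("r", "ALAL", structure="HHHH")
        res = t_omega_ratio(rec, ["AL", "LA"])
        assert not res.defined and res.r is None

    def test_invariant_to_non_loop_content(self):
        base = SequenceRecord("r", "ALALGG", structure="TT  HH")
        more = SequenceRecord("r", "ALALGGGG", structure="TT  HHHH")
        e = ["AL", "LA", "GG"]
        assert t_omega_ratio(base, e).r == t_omega_ratio(more, e).r


class TestExchangeGroups:
    def test_partition_of_twenty(self):
        sizes = sorted(len(v) for v in EXCHANGE_GROUPS.values())
        assert sizes == [5, 7, 8]
        assert set().union(*EXCHANGE_GROUPS.values()) == set(
            "ACDEFGHIKLMNPQRSTVWY")

    def _records(self, scale=1.0, seed=0):
        """Sequences whose helix regions are dominated by group-H residues,
        with jitter; group separation scales with `scale`."""
        rng = np.random.default_rng(seed)
        records = []
        h_pool = sorted(EXCHANGE_GROUPS["H"])
        t_pool = sorted(EXCHANGE_GROUPS["T"])
        e_pool = sorted(EXCHANGE_GROUPS["E"])
        for i in range(6):
            n = 40
            k_h = int(n * (0.34 + scale * 0.3)) % (n + 1)
            k_t = int((n - k_h) * 0.5)
            k_e = n - k_h - k_t
            residues = "".join(
                [h_pool[int(j)] for j in rng.integers(0, len(h_pool), k_h)]
                + [t_pool[int(j)] for j in rng.integers(0, len(t_pool), k_t)]
                + [e_pool[int(j)] for j in rng.integers(0, len(e_pool), k_e)]
            )
            # jitter composition slightly
            extra = "".join(
                [h_pool[int(j)] for j in rng.integers(0, len(h_pool),
                                                      int(rng.integers(0, 3)))]
            )
            residues += extra
            records.append(SequenceRecord(
                f"s{i}", residues, structure="H" * len(residues)))
        return records

    def test_f_matches_hand_sum_of_squares(self):
        records = self._records(scale=0.5)
        results = exchange_group_analysis(records)
        res = results[0]
        # hand computation from the same per-sequence frequencies
        freqs = {g: [] for g in EXCHANGE_GROUPS}
        lookup = {aa: g for g, m in EXCHANGE_GROUPS.items() for aa in m}
        for rec in records:
            counts = {g: 0 for g in EXCHANGE_GROUPS}
            for aa in rec.residues:
                counts[lookup[aa]] += 1
            for g in counts:
                freqs[g].append(counts[g] / len(rec.residues))
        samples = [np.array(freqs[g]) for g in sorted(freqs)]
        grand = np.mean(np.concatenate(samples))
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        df_b = len(samples) - 1
        df_w = sum(len(s) for s in samples) - len(samples)
        f_hand = (ss_between / df_b) / (ss_within / df_w)
        assert res.f == pytest.approx(f_hand)

    def test_separated_groups_get_distinct_letters(self):
        results = exchange_group_analysis(self._records(scale=1.5))
        res = results[0]
        assert res.p < 0.05
        assert res.letters["H"] != res.letters["T"] or \
            res.letters["H"] != res.letters["E"]

    def test_identical_groups_share_letter(self):
        # eight residues from each group in every sequence -> all group
        # frequencies equal (1/3) and constant across sequences
        records = []
        for i in range(4):
            residues = "LKFEQLKF" + "SPTARCGW" + "YMIVNDHY"
            records.append(SequenceRecord(
                f"s{i}", residues, structure="H" * len(residues)))
        results = exchange_group_analysis(records)
        res = results[0]
        assert res.f == pytest.approx(0.0)
        assert len(set(res.letters.values())) == 1
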