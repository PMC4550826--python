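"""Data model, table I/O, SE derivation and allele harmonization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telomr.errors import (
    AlleleMismatchError,
    DomainError,
    EmptyInstrumentError,
    PalindromicAlleleError,
    SummaryFormatError,
)
from telomr.summary_io import (
    COMPLEMENT,
    SnpExposureAssoc,
    SnpOutcomeAssoc,
    build_instrument_set,
    derive_se_from_p,
    harmonize,
    read_exposure_table,
    read_outcome_table,
    telomere_instruments,
    two_sided_p,
    write_exposure_table,
    write_outcome_table,
)
from telomr.synthetic_data import SyntheticConfig, generate_dataset


class TestPackagedInstrumentTable:
    def test_eleven_records_two_ld_marked(self):
        records = telomere_instruments()
        assert len(records) == 11
        marked = {r.snp_id for r in records if not r.active}
        assert marked == {"rs7726159", "rs412658"}
        assert len(telomere_instruments(active_only=True)) == 9

    def test_terc_row_parses_verbatim(self):
        terc = {r.snp_id: r for r in telomere_instruments()}["rs10936599"]
        assert terc.long_allele == "C"
        assert terc.beta_kb == pytest.approx(0.117)
        assert terc.p_value == pytest.approx(2.5e-31)
        assert terc.locus == "TERC"

    def test_reserializes_losslessly(self, tmp_path):
        records = telomere_instruments()
        path = tmp_path / "roundtrip.tsv"
        write_exposure_table(records, path)
        assert read_exposure_table(path) == records


class TestReaders:
    def test_header_only_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snp_id\tlong_allele\tbeta_kb\tp_value\n")
        assert read_exposure_table(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp_id\tlong_allele\tp_value\nrs1\tA\t0.01\n")
        with pytest.raises(SummaryFormatError, match="beta_kb"):
            read_exposure_table(path)

    def test_nonpositive_beta_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("snp_id\tlong_allele\tbeta_kb\tp_value\n"
                        "rs1\tA\t-0.1\t0.01\n")
        with pytest.raises(DomainError, match="beta_kb"):
            read_exposure_table(path)

    def test_dialect_maps_foreign_headers(self, tmp_path):
        path = tmp_path / "foreign.tsv"
        path.write_text("rsid\tEA\tb\tpval\nrs1\tA\t0.1\t0.01\n")
        dialect = {"snp_id": "rsid", "long_allele": "EA",
                   "beta_kb": "b", "p_value": "pval"}
        (rec,) = read_exposure_table(path, dialect)
        assert rec.snp_id == "rs1" and rec.beta_kb == 0.1

    def test_outcome_roundtrip(self, tmp_path):
        _, outcomes, _ = generate_dataset(SyntheticConfig(seed=3))
        path = tmp_path / "out.tsv"
        write_outcome_table(outcomes, path)
        assert read_outcome_table(path) == outcomes


class TestDeriveSeFromP:
    def test_unit_z_score(self):
        p = 2 * (1 - 0.8413447460685429)  # 2*(1 - Phi(1))
        assert derive_se_from_p(1.0, p) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("beta, p, expected", [
        (0.117, 2.5e-31, 0.0100492),   # TERC instrument
        (0.094, 4.4e-19, 0.0105305),   # TERT instrument
    ])
    def test_instrument_scale_values(self, beta, p, expected):
        assert derive_se_from_p(beta, p) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("beta, p", [
        (0.0, 0.05), (0.1, 0.0), (0.1, 1.0), (0.1, 1.5), (0.1, 1e-310),
    ])
    def test_domain_errors(self, beta, p):
        with pytest.raises(DomainError):
            derive_se_from_p(beta, p)

    @settings(derandomize=True, max_examples=200)
    @given(beta=st.floats(0.001, 10.0),
           p=st.floats(1e-300, 0.999))
    def test_roundtrips_with_wald_p(self, beta, p):
        se = derive_se_from_p(beta, p)
        assert two_sided_p(beta, se) == pytest.approx(p, rel=1e-10)


def _exposure(snp="rs1", allele="C", beta=0.1, p=1e-10):
    return SnpExposureAssoc(snp_id=snp, long_allele=allele, beta_kb=beta,
                            p_value=p)


class TestHarmonize:
    def test_effect_allele_matches_long(self):
        v = harmonize(_exposure(), SnpOutcomeAssoc(
            snp_id="rs1", effect_allele="C", other_allele="T",
            beta_logodds=0.05, se_logodds=0.02))
        assert v.y == 0.05 and not v.flipped
        assert v.sigma_x == pytest.approx(derive_se_from_p(0.1, 1e-10))

    def test_other_allele_matches_long_flips_sign(self):
        v = harmonize(_exposure(), SnpOutcomeAssoc(
            snp_id="rs1", effect_allele="T", other_allele="C",
            beta_logodds=0.05, se_logodds=0.02))
        assert v.y == -0.05 and v.flipped

    @pytest.mark.parametrize("effect", sorted(COMPLEMENT))
    def test_palindromic_pairs_error_by_default(self, effect):
        out = SnpOutcomeAssoc(snp_id="rs1", effect_allele=effect,
                              other_allele=COMPLEMENT[effect],
                              beta_logodds=0.05, se_logodds=0.02)
        exp = _exposure(allele=effect)
        with pytest.raises(PalindromicAlleleError):
            harmonize(exp, out)
        # opt-in pass-through trusts the stated orientation
        v = harmonize(exp, out, allow_palindromic=True)
        assert v.y == 0.05

    def test_neither_allele_matches(self):
        with pytest.raises(AlleleMismatchError):
            harmonize(_exposure(allele="G"), SnpOutcomeAssoc(
                snp_id="rs1", effect_allele="C", other_allele="T",
                beta_logodds=0.05, se_logodds=0.02))

    def test_flip_involution(self):
        out = SnpOutcomeAssoc(snp_id="rs1", effect_allele="C",
                              other_allele="T", beta_logodds=0.05,
                              se_logodds=0.02)
        swapped = dataclasses.replace(out, effect_allele="T",
                                      other_allele="C", beta_logodds=-0.05)
        v, w = harmonize(_exposure(), out), harmonize(_exposure(), swapped)
        assert dataclasses.replace(w, flipped=v.flipped) == v
        assert w.flipped != v.flipped


class TestBuildInstrumentSet:
    @pytest.fixture
    def tables(self):
        exposures, outcomes, _ = generate_dataset(SyntheticConfig(seed=5))
        return exposures, outcomes

    def test_full_join_keeps_all_nine(self, tables):
        exposures, outcomes = tables
        iset = build_instrument_set(exposures, outcomes)
        assert len(iset) == 9 and iset.excluded == []
        assert iset.snp_ids == [e.snp_id for e in exposures]

    def test_ld_marked_rows_dropped_with_reason(self, tables):
        _, outcomes = tables
        iset = build_instrument_set(telomere_instruments(), outcomes)
        dropped = dict(iset.excluded)
        assert set(dropped) == {"rs7726159", "rs412658"}
        assert "rs2736100" in dropped["rs7726159"]

    def test_user_exclusion(self, tables):
        exposures, outcomes = tables
        iset = build_instrument_set(exposures, outcomes,
                                    exclusions={"rs6772228": "strict"})
        assert len(iset) == 8
        assert ("rs6772228", "strict") in iset.excluded

    def test_missing_in_outcome_logged_not_fatal(self, tables):
        exposures, outcomes = tables
        partial = [o for o in outcomes if o.snp_id != "rs3027234"]
        iset = build_instrument_set(exposures, partial)
        assert len(iset) == 8
        assert ("rs3027234", "missing-in-outcome") in iset.excluded

    def test_proxy_substitution(self, tables):
        exposures, outcomes = tables
        renamed = [dataclasses.replace(o, snp_id="rs999proxy")
                   if o.snp_id == "rs3027234" else o for o in outcomes]
        iset = build_instrument_set(exposures, renamed,
                                    proxy_map={"rs3027234": "rs999proxy"})
        assert len(iset) == 9 and "rs3027234" in iset.snp_ids

    def test_empty_result_raises(self, tables):
        exposures, _ = tables
        with pytest.raises(EmptyInstrumentError):
            build_instrument_set(exposures, [])
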