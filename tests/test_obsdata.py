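"""Data model, CSV I/O and community-matrix assembly."""

import random

import numpy as np
import pytest

from lander import obsdata
from lander.errors import ParseError, ValidationError
from lander.obsdata import (
    DeploymentRecord,
    SpeciesObservation,
    build_community_matrix,
    first_arrival_table,
    is_fish,
    load_deployments,
    load_observations,
    write_deployments,
    write_observations,
)

FIXTURE_DEPTHS = {532, 737, 943, 1346, 1823, 3396, 4204, 5111}


def _mk_deployment(id="d1", depth=1000.0, study="test", **kw):
    defaults = dict(
        latitude=36.0, longitude=21.0, date=__import__("datetime").date(2011, 1, 1),
        duration=5.0, orientation="vertical",
    )
    defaults.update(kw)
    return DeploymentRecord(id=id, depth=depth, study=study, **defaults)


class TestBundledFixture:
    def test_deployment_depths(self, study_deployments):
        assert len(study_deployments) == 8
        assert {int(d.depth) for d in study_deployments} == FIXTURE_DEPTHS

    def test_observation_count_and_known_record(self, study_observations):
        # 25 bold N_max cells over the 14 taxa of the source table
        assert len(study_observations) == 25
        assert len({o.taxon for o in study_observations}) == 14
        rec = next(
            o for o in study_observations
            if o.deployment_id == "8" and o.taxon == "Coryphaenoides mediterraneus"
        )
        assert (rec.n_max, rec.t_arr, rec.pct_images) == (1, 174.0, 0.4)

    def test_matrix_shape_and_anchor_cell(self, study_matrix):
        assert study_matrix.data.shape == (8, 14)
        # deployment 7 (4204 m) held the Acanthephyra abundance peak
        assert study_matrix.data.loc["7", "Acanthephyra eximia"] == 29
        # rows ordered by increasing depth
        assert study_matrix.sample_ids == [str(i) for i in range(1, 9)]

    def test_no_taxon_overlap_across_1000m(self, study_matrix):
        shallow = study_matrix.data.loc[["1", "2", "3"]]
        deep = study_matrix.data.loc[["4", "5", "6", "7", "8"]]
        shared = (shallow.sum() > 0) & (deep.sum() > 0)
        assert not shared.any()


class TestLoading:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "deployments.csv"
        p.write_text(",".join(obsdata.DEPLOYMENT_COLUMNS) + "\n")
        assert load_deployments(p) == []

    def test_negative_depth_rejected(self, tmp_path):
        p = tmp_path / "deployments.csv"
        p.write_text(
            ",".join(obsdata.DEPLOYMENT_COLUMNS)
            + "\nd1,-10,36,21,2011-01-01,5,vertical,,,,test\n"
        )
        with pytest.raises(ValidationError):
            load_deployments(p)

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "deployments.csv"
        p.write_text(
            ",".join(obsdata.DEPLOYMENT_COLUMNS)
            + "\nd1,abc,36,21,2011-01-01,5,vertical,,,,test\n"
        )
        with pytest.raises(ParseError, match=r"row 2.*depth_m"):
            load_deployments(p)

    def test_duplicate_id_within_study(self, tmp_path):
        p = tmp_path / "deployments.csv"
        row = "d1,100,36,21,2011-01-01,5,vertical,,,,test\n"
        p.write_text(",".join(obsdata.DEPLOYMENT_COLUMNS) + "\n" + row + row)
        with pytest.raises(ValidationError, match="duplicate"):
            load_deployments(p)

    def test_zero_nmax_rejected(self, tmp_path):
        p = tmp_path / "observations.csv"
        p.write_text("deployment_id,taxon,n_max,t_arr_min,pct_images\nd1,Conger conger,0,4,6.5\n")
        with pytest.raises(ValidationError, match="n_max"):
            load_observations(p)

    def test_duplicate_observation_rejected(self, tmp_path):
        p = tmp_path / "observations.csv"
        row = "d1,Conger conger,1,4,6.5\n"
        p.write_text("deployment_id,taxon,n_max,t_arr_min,pct_images\n" + row + row)
        with pytest.raises(ValidationError, match="duplicate"):
            load_observations(p)

    def test_round_trip(self, tmp_path, study_deployments, study_observations):
        pd_path, po_path = tmp_path / "d.csv", tmp_path / "o.csv"
        write_deployments(study_deployments, pd_path)
        write_observations(study_observations, po_path)
        assert load_deployments(pd_path) == study_deployments
        assert load_observations(po_path) == study_observations


class TestMatrixAssembly:
    def test_single_observation_identity(self):
        dep = [_mk_deployment()]
        obs = [SpeciesObservation("d1", "Conger conger", 3, 4.0, 6.5)]
        m = build_community_matrix(obs, dep)
        assert m.data.shape == (1, 1)
        assert m.data.iloc[0, 0] == 3

    def test_orphan_deployment_rejected(self):
        with pytest.raises(ValidationError, match="unknown deployment"):
            build_community_matrix(
                [SpeciesObservation("ghost", "Conger conger", 1, 4.0, 6.5)], [_mk_deployment()]
            )

    def test_cell_sum_equals_observation_sum(self, study_matrix, study_observations):
        assert study_matrix.values.sum() == sum(o.n_max for o in study_observations)

    def test_zero_iff_no_observation(self, study_matrix, study_observations):
        observed = {(o.deployment_id, o.taxon) for o in study_observations}
        for sid in study_matrix.sample_ids:
            for taxon in study_matrix.taxa:
                cell = study_matrix.data.loc[sid, taxon]
                assert (cell == 0) == ((sid, taxon) not in observed)

    def test_shuffle_invariance(self, study_deployments, study_observations):
        base = build_community_matrix(study_observations, study_deployments)
        shuffled = list(study_observations)
        random.Random(3).shuffle(shuffled)
        m = build_community_matrix(shuffled, study_deployments)
        # identical up to the documented column rule (first appearance order)
        assert sorted(m.taxa) == sorted(base.taxa)
        assert m.sample_ids == base.sample_ids
        assert m.data[base.taxa].equals(base.data)

    def test_merging_studies_unions_taxa_zero_filled(self):
        dep = [
            _mk_deployment("a1", 500, study="A"),
            _mk_deployment("b1", 1500, study="B"),
        ]
        obs = [
            SpeciesObservation("a1", "Conger conger", 2, 4.0, 6.5),
            SpeciesObservation("b1", "Acanthephyra eximia", 5, 2.0, 89.0),
        ]
        m = build_community_matrix(obs, dep)
        assert set(m.taxa) == {"Conger conger", "Acanthephyra eximia"}
        assert m.data.loc["a1", "Acanthephyra eximia"] == 0
        assert m.data.loc["b1", "Conger conger"] == 0

    def test_case_insensitive_taxon_matching(self):
        dep = [_mk_deployment("d1", 500), _mk_deployment("d2", 700)]
        obs = [
            SpeciesObservation("d1", "Conger  conger", 1, 4.0, 6.5),
            SpeciesObservation("d2", "conger conger", 2, 9.0, 1.5),
        ]
        m = build_community_matrix(obs, dep)
        assert m.data.shape == (2, 1)


class TestFirstArrival:
    def test_first_fish_at_deepest_deployment(self, study_observations, study_deployments):
        table = first_arrival_table(study_observations, study_deployments, is_fish)
        row = table[table.deployment_id == "8"].iloc[0]
        assert row.t_arr_min == 174.0  # the grenadier, 2.9 h after touchdown

    def test_all_taxa_filter_uses_shrimp_arrival(self, study_observations, study_deployments):
        table = first_arrival_table(study_observations, study_deployments, lambda t: True)
        row = table[table.deployment_id == "8"].iloc[0]
        assert row.t_arr_min == 1.0  # Acanthephyra immediately present on landing

    def test_deployment_without_qualifying_taxa_omitted(self):
        dep = [_mk_deployment("d1", 500), _mk_deployment("d2", 700)]
        obs = [
            SpeciesObservation("d1", "Acanthephyra eximia", 1, 5.0, 10.0),  # decapod only
            SpeciesObservation("d2", "Conger conger", 1, 4.0, 6.5),
        ]
        table = first_arrival_table(obs, dep, is_fish)
        assert list(table.deployment_id) == ["d2"]
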