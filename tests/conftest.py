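import pytest

from mlclonal import mutmatrix, simdata
from mlclonal.io_formats import MutationRecord, SampleManifest

A_REGIONS = ["HCC-A1", "HCC-A2", "HCC-A3"]
B_REGIONS = ["HCC-B1", "HCC-B2", "HCC-B3"]
C_REGIONS = ["ICC-C1", "ICC-C2", "ICC-C3"]
IMS = ["IM1", "IM2"]


@pytest.fixture(scope="session")
def patient():
    return simdata.generate_case_fixture()


@pytest.fixture(scope="session")
def fixture_matrix(patient):
    return mutmatrix.build_matrix(patient.records, patient.manifest)


def make_manifest(tumors, recurrences=()):
    """Manifest builder: tumors maps tumor id -> list of region sample ids."""
    rows = []
    for tumor, samples in tumors.items():
        stype = "recurrence" if tumor in recurrences else "primary_region"
        for i, s in enumerate(samples):
            rows.append((s, tumor, f"R{i + 1}", stype, 1 if tumor in recurrences else 0))
    rows.append(("NORMAL", "", "", "normal", 0))
    return SampleManifest.from_records(rows)


def make_records(pattern_map, manifest, present=(70, 30), absent=(100, 0),
                 func_class="nonsynonymous"):
    """One MutationRecord per pattern entry: mutation id -> set of samples present."""
    records = []
    for i, (name, samples) in enumerate(sorted(pattern_map.items())):
        depths = {}
        for s in manifest.samples:
            depths[s] = present if s in samples else absent
        records.append(MutationRecord(
            chrom="chr1", pos=1000 + i, ref="C", alt="T", gene=name,
            func_class=func_class, depths=depths))
    return records


def make_matrix(pattern_map, manifest, **kwargs):
    return mutmatrix.build_matrix(
        make_records(pattern_map, manifest, **kwargs), manifest)
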