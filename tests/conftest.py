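import numpy as np
import pytest

from gdrep.io import ChainRecord, PairedCell


def make_chain(
    cell_id="cell-1",
    locus="TRG",
    v_call="TRGV7",
    j_call="TRGJ1",
    cdr3_nt="TGTGCTAGT",
    cdr3_aa="CAS",
    productive=True,
    umi_count=3,
    contig_id=None,
    sample_id="KO_ileum",
    genotype="KO",
    segment="ileum",
):
    if locus == "TRD" and v_call.startswith("TRGV"):
        v_call, j_call = "TRDV5", "TRDJ1"
    if contig_id is None:
        contig_id = f"{cell_id}_{locus}"
    return ChainRecord(
        cell_id=cell_id,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
        umi_count=umi_count,
        contig_id=contig_id,
        sample_id=sample_id,
        genotype=genotype,
        segment=segment,
    )


def make_paired_cell(cell_id="cell-1", gamma_aa="CAS", delta_aa="CAT", sample_id="KO_ileum",
                     gamma_v="TRGV7", delta_v="TRDV5", gamma=True, delta=True):
    g = make_chain(cell_id=cell_id, locus="TRG", v_call=gamma_v, cdr3_aa=gamma_aa,
                   cdr3_nt="", sample_id=sample_id) if gamma else None
    d = make_chain(cell_id=cell_id, locus="TRD", v_call=delta_v, cdr3_aa=delta_aa,
                   cdr3_nt="", sample_id=sample_id) if delta else None
    return PairedCell(cell_id=cell_id, sample_id=sample_id, gamma=g, delta=d)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
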