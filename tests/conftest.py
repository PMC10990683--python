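"""Shared fixtures: toy SBML models, printed-table rows, synthetic corpora."""

import pytest

from cytonet import (
    ExpressionGroundTruth,
    SbmlGroundTruth,
    load_expression_table,
    make_expression_table,
    make_sbml_corpus,
    parse_sbml,
)

TOY_AB = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="toy" name="toy decay">
  <listOfCompartments><compartment id="cytosol" constant="true"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" name="substrate A" compartment="cytosol" sboTerm="SBO:0000252"
            initialConcentration="1.0">
    <annotation>
     <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#">
      <rdf:Description>
       <rdf:Bag>
        <rdf:li rdf:resource="https://identifiers.org/uniprot/P09016"/>
       </rdf:Bag>
      </rdf:Description>
     </rdf:RDF>
    </annotation>
   </species>
   <species id="B" name="product B" compartment="cytosol"
            initialConcentration="0.0"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" name="A to B" reversible="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""

# linear chain R1-R2-R3 coupled through shared species, plus one isolated
# species and one modifier
TOY_CHAIN = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="chain" name="toy chain">
  <listOfSpecies>
   <species id="S1" name="one"/>
   <species id="S2" name="two"/>
   <species id="S3" name="three"/>
   <species id="S4" name="four"/>
   <species id="M" name="helper enzyme"/>
   <species id="LONER" name="unreferenced"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" reversible="false">
    <listOfReactants><speciesReference species="S1"/></listOfReactants>
    <listOfProducts><speciesReference species="S2"/></listOfProducts>
   </reaction>
   <reaction id="R2" reversible="false">
    <listOfReactants><speciesReference species="S2"/></listOfReactants>
    <listOfProducts><speciesReference species="S3"/></listOfProducts>
    <listOfModifiers><modifierSpeciesReference species="M"/></listOfModifiers>
   </reaction>
   <reaction id="R3" reversible="false">
    <listOfReactants><speciesReference species="S3"/></listOfReactants>
    <listOfProducts><speciesReference species="S4"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""

EXPR_HEADER = "Gene\tGene.name\tTissue\tCluster\tCell.type\tRead.count\tnTPM"

# the six printed placenta rows (clusters distinguish the duplicated lineage)
TABLE1_TSV = "\n".join([
    EXPR_HEADER,
    "ENSG00000000003\tTSPAN6\tPlacenta\tc-1\tsmooth muscle cells\t100\t62.3",
    "ENSG00000000003\tTSPAN6\tPlacenta\tc-1\tt-cells\t100\t3.3",
    "ENSG00000000003\tTSPAN6\tPlacenta\tc-2\tsmooth muscle cells\t100\t19.3",
    "ENSG00000000003\tTSPAN6\tPlacenta\tc-1\tendothelial cells\t100\t50.1",
    "ENSG00000000003\tTSPAN6\tPlacenta\tc-1\tfibroblasts\t100\t44.9",
    "ENSG00000000003\tTSPAN6\tPlacenta\tc-1\tmixed immune cells\t100\t11.7",
]) + "\n"

# the printed small-intestine DEFA5 cluster replicates
DEFA5_TSV = "\n".join([
    EXPR_HEADER,
    "ENSG00000164816\tDEFA5\tSmall intestine\tc-1\tundifferentiated cells\t10\t882",
    "ENSG00000164816\tDEFA5\tSmall intestine\tc-2\tundifferentiated cells\t10\t5116.4",
    "ENSG00000164816\tDEFA5\tSmall intestine\tc-3\tundifferentiated cells\t10\t941045",
]) + "\n"

HGNC_CSV = "\n".join([
    "symbol,ensembl_gene_id,uniprot_ids,name,locus_type",
    'HOXD4,ENSG00000170166,P09016,"homeobox D4",gene with protein product',
    'DKK1,ENSG00000107984,O94907,"dickkopf WNT signaling pathway inhibitor 1",'
    "gene with protein product",
    'TSPAN6,ENSG00000000003,"O43657",tetraspanin 6,gene with protein product',
    'NOENS,,Q99999 Q99998,"no ensembl entry",gene with protein product',
]) + "\n"

SBO_TSV = "\n".join([
    "SBO:0000297\tprotein complex",
    "SBO:0000252\tpolypeptide chain",
    "SBO:0000247\tsimple chemical",
]) + "\n"


@pytest.fixture
def toy_ab():
    return parse_sbml(TOY_AB)


@pytest.fixture
def toy_chain():
    return parse_sbml(TOY_CHAIN)


@pytest.fixture
def table1_records():
    return load_expression_table(TABLE1_TSV)


@pytest.fixture
def defa5_records():
    return load_expression_table(DEFA5_TSV)


@pytest.fixture(scope="session")
def synth_expression():
    """Default-condition synthetic expression table + manifest (seed 0)."""
    truth = ExpressionGroundTruth(seed=0)
    tsv_text, manifest = make_expression_table(truth)
    return tsv_text, manifest


@pytest.fixture(scope="session")
def synth_corpus():
    """Default-condition synthetic SBML corpus + manifest (seed 0)."""
    truth = SbmlGroundTruth(seed=0)
    files, manifest = make_sbml_corpus(truth)
    return files, manifest
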