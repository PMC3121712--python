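name	iri
molecular entity	http://purl.org/obo/owl/CHEBI#CHEBI_23367
molecule	http://purl.org/obo/owl/CHEBI#CHEBI_25367
primary alcohol	http://purl.org/obo/owl/CHEBI#CHEBI_15734
organic group	http://purl.org/obo/owl/CHEBI#CHEBI_33247
functional group	http://purl.org/obo/owl/CHEBI#CHEBI_33249
atom	http://purl.org/obo/owl/CHEBI#CHEBI_33250
hydrogen atom	http://purl.org/obo/owl/CHEBI#CHEBI_49637
carbon atom	http://purl.org/obo/owl/CHEBI#CHEBI_27594
oxygen atom	http://purl.org/obo/owl/CHEBI#CHEBI_25805
nitrogen atom	http://purl.org/obo/owl/CHEBI#CHEBI_25555
sulfur atom	http://purl.org/obo/owl/CHEBI#CHEBI_26833
phosphorus atom	http://purl.org/obo/owl/CHEBI#CHEBI_28659
fluorine atom	http://purl.org/obo/owl/CHEBI#CHEBI_24061
chlorine atom	http://purl.org/obo/owl/CHEBI#CHEBI_23116
bromine atom	http://purl.org/obo/owl/CHEBI#CHEBI_22927
iodine atom	http://purl.org/obo/owl/CHEBI#CHEBI_24859
ruthenium atom	http://purl.org/obo/owl/CHEBI#CHEBI_30682
aluminium atom	http://purl.org/obo/owl/CHEBI#CHEBI_28984
covalent bond	http://semanticscience.org/resource/SIO_011118
single bond	http://semanticscience.org/resource/SIO_010498
double bond	http://semanticscience.org/resource/CHESS_DoubleBond
triple bond	http://semanticscience.org/resource/CHESS_TripleBond
aromatic bond	http://semanticscience.org/resource/CHESS_AromaticBond
chemical reaction	http://semanticscience.org/resource/SIO_010345
chemical configuration	http://semanticscience.org/resource/SIO_000659
has proper part	http://semanticscience.org/resource/SIO_000053
is part of	http://semanticscience.org/resource/CHESS_isPartOf
has input	http://semanticscience.org/resource/SIO_000230
has product	http://semanticscience.org/resource/SIO_000312
has agent	http://semanticscience.org/resource/SIO_000139
transforms into	http://semanticscience.org/resource/SIO_000655
has value	http://semanticscience.org/resource/CHESS_hasValue
has unit	http://semanticscience.org/resource/CHESS_hasUnit
has uncertainty	http://semanticscience.org/resource/CHESS_hasUncertainty
has attribute	http://semanticscience.org/resource/CHESS_hasAttribute
has direct part	http://semanticscience.org/resource/CHESS_hasDirectPart
has provider	http://semanticscience.org/resource/CHESS_hasProvider
has participant	http://semanticscience.org/resource/CHESS_hasParticipant
has stoichiometric coefficient	http://semanticscience.org/resource/CHESS_hasStoichiometricCoefficient
in reaction	http://semanticscience.org/resource/CHESS_inReaction
is specified output of	http://semanticscience.org/resource/CHESS_isSpecifiedOutputOf
is output of	http://semanticscience.org/resource/CHESS_isOutputOf
software application	http://semanticscience.org/resource/CHESS_SoftwareApplication
software version	http://semanticscience.org/resource/CHESS_SoftwareVersion
has single bond with	http://semanticscience.org/resource/CHESS_hasSingleBondWith
has double bond with	http://semanticscience.org/resource/CHESS_hasDoubleBondWith
has triple bond with	http://semanticscience.org/resource/CHESS_hasTripleBondWith
has aromatic bond with	http://semanticscience.org/resource/CHESS_hasAromaticBondWith
bond dissociation energy descriptor	http://semanticscience.org/resource/CHEMINF_000252
algorithm	http://semanticscience.org/resource/CHEMINF_000144
parameterized software execution	http://semanticscience.org/resource/CHEMINF_000147
mass descriptor	http://semanticscience.org/resource/CHESS_MassDescriptor
hydrogen bond acceptor count	http://semanticscience.org/resource/CHESS_HydrogenBondAcceptorCount
hydrogen bond donor count	http://semanticscience.org/resource/CHESS_HydrogenBondDonorCount
logP descriptor	http://semanticscience.org/resource/CHESS_LogPDescriptor
heavy atom count	http://semanticscience.org/resource/CHESS_HeavyAtomCount
3D cartesian coordinate	http://semanticscience.org/resource/CHESS_Cartesian3DCoordinate
x cartesian coordinate	http://semanticscience.org/resource/CHESS_XCartesianCoordinate
y cartesian coordinate	http://semanticscience.org/resource/CHESS_YCartesianCoordinate
z cartesian coordinate	http://semanticscience.org/resource/CHESS_ZCartesianCoordinate
temperature	http://semanticscience.org/resource/CHESS_Temperature
kelvin	http://purl.org/obo/owl/UO#UO_0000012
angstrom	http://purl.org/obo/owl/UO#UO_0000019
has formal charge	http://semanticscience.org/resource/CHESS_hasFormalCharge
has isotope	http://semanticscience.org/resource/CHESS_hasIsotope
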