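"""Packaged reference constants.

``BOVINE_RH1`` is the bovine rhodopsin protein (RefSeq accession
NP_001014890, 348 residues).  Spectral-tuning site numbering throughout the
package refers to positions in this sequence (1-based), the community
standard for visual-pigment critical sites.
"""

BOVINE_RH1_ACCESSION = "NP_001014890"

BOVINE_RH1 = (
    "MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLYVTVQHKKLRTPLNYILLNLAVADLFMVFGGFTTTLYTSLHGYFVFGPTGCNLEGFFATLGGEIALWSLVVLAIERYVVVCKPMSNFRFGENHAIMGVAFTWVMALACAAPPLVGWSRYIPEGMQCSCGIDYYTPHEETNNESFVIYMFVVHFIIPLIVIFFCYGQLVFTVKEAAAQQQESATTQKAEKEVTRMVIIMVIAFLICWLPYAGVAFYIFTHQGSDFGPIFMTIPAFFAKTSAVYNPVIYIMMNKQFRNCMVTTLCCGKNPLGDDEASTTVSKTETSQVAPA"
)
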