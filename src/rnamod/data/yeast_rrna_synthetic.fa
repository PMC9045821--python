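>18S
GGAGCAGAGCUAACGGCAUUCGCCUGGUGUAAGAACGAACCUUAUGGCUGGCUCACCGGCGUUUUGUCCCAGGAAGGUUC
AGUUAUGCUUGUGAUGUUCAACAAUUGCCGUUUGAAAUUGGGUCUGGUCAUGUACUCGGGCGAGCACUUUGCAAAUGGUA
AGCCGAGCGCCCACCGCGGAGUAGUAGGCAGACAGCAUCAACGCCCAUGAGGAUCUCUCGCCGUGCCCGAUCUAAAAAUG
GGCUAAUCGGUAACUCAGUUGCUGACGUAUGAGUUAAGCGCCGAAAAAUCGUAGGACUUAGAGCAACACAGUGGACUGGU
AGGGCGAUCAAAUGUUAAGCGGUUGUGGUGACAUCACUGGUGUACCUGUCUUGCGCUGUUUACCGUCGCAAUAUGCCGAU
CGUAAUUGGGGUUACUGCGUCGAAUCGUCCUGCUCAUGCGCAACGAGGAACGAUAUGGCACCCACGAUUAUUGGUGGGAA
AAAUUCAAAAUCCCCCGGCUAAUGUUCGUCACCGCUGACCUUCAUCUUAAGUAGGGACCAAAAGCCGAGUUUUAUUCUGC
AUCUCUCAGCCAUUAGUCCGUAAUGGGUCGGUAGAGCUAUGCGUGAAAUGCUUCUCCCAAGCUUUUCUCGCUGAGAGGAA
GGCGCGUGAACCCCUUCAGUGCGACGCUUGAGUCGGAUCAUAAGAAGGCCUUUCCACGUUCUUCCUACAGAGCCAUAACC
AGGAGGAAACUGUAUCGUUCUUAACCUCGGCAAUCUGGUUGGGCCUAUCUGGCCUGGACUCCACUAUCUAGAUAAAGCAU
AACCGCUUAAUUAAUGGGUCCCGUACAAUCCUCAUCAGCUGGCCGUAUGCUGCUCUUCAGGAUGUGUUUUCACUCCCCCA
GGGCUCGGUUUUAUUAGACGGUGUCGCCUCCGUGAAUCUAGUAACGCGGACUAUAUAAAAGGAUAGUCUGUGGUUCGUCG
AGUCACGGGUCGUAUUUUCCUACAGAAAUAUCCUUCCUUCCUGUGCAGUAACAUUACAGCCUCGUCAUACGUAAUACCCC
ACGAUAUGUAAGGCUCAUUGUUAAGCUGAAAUCGGCGACACGUUCGGGGUUGGCAGCCAGGCUUUGGGUCACGUCGGGCU
AUAAUUACCUCGAAGUCUAUUCCAUAUGCUCGGCUCAGGGGGAACAUUGCGGAUGAGGUUGCACCGCCUAUAAAGGUGAU
CUCACCAGCCGGCUUUCAUGCUUCAAAGCGCAGCCGAUAUGGAGCCGUCUCGGCUGAGAUGGGUCAUCUAGUUGCGCGCC
UUCACAGGUUUUGGGAGGAUGCGGUCAAAGCAGUUGUUCCAAAAGAAGUAAAGGUCGGAAGUGUUUGAUCACAUCUUACG
ACUUUUUACUUUUCUUAGAGUAGCGUAGCUUUGGUGGCACAGGUUUGCGGGGUCUAUGGCCCUCGCCCCAAACGAUGGUC
CAACGCAAUAAGAACCCGGGUCGUUGAUCACCGUACGAAAUACAACGGUCUUAGCGUGACCACGUGUCUAGAAGUAGACU
GCUUCGUCCAUCUUGUGGCCAGUAGCAAAUCCUGCGAAAUAACAAAGCAUUCUGCCGCAUAGCCCGACUAGGGCAUACGU
AAAACCUCUGGUGAUCUUAGGUUCCUUCGACGCUCGCGCGGCCUCAGUGCCAAAUUUACUUUUGCAACAUACUAUAGGUC
GUACAUGGCUAGAAGACCUUGAAUCCGGAAAAAAGUUCGAAUUUCUCCUACAGGGUCUACCCGUAUGGCGAGUUAUCUGU
UUGUGGCCUUAUCUGAGGGUGACUAAGGGAAAGUAUCUUA
>25S
UUGGAGUGGGGUCGUCUCCUCACUGUUAGCGGAAGAAAUGAUCAUUGGAAAUACACACGUAUUACAAGUCCAGCAUUGUC
GGUCGGUUCCGAGCACCAGCCGAAGACACAAAUUCUGCGGCUUGUCCUGUUCACAGCACUAGUUUGUGUAGAUCAUAGGA
UUAUAUAUGUGGUAUGCAUGUUUUUCGCCGACUUGGGCUAGGCCCACACUAUGGCAUAAGCCUAGGCACCGCGCCUAGGA
GGAAACCUCCUAUUUGCGUCCUUUUUUUCGUUCUCUACGAGCCUGUUGACAUAUACUGCACUGGGUUCAAAGAUGGCUUU
GCUACCUUCGGCAUCAAGUGAACCCAUCCGAAGUCUAACCUAAGGAAAAUUCACCUGUGACCAAUACCGAAGGGAACUGC
UGCCAUCACCUCCCCACGGAGUCUCCAUACUUACGGGUGUCUUAGUACGGAGAUCAAUCUUGCGAUAGAACAUUGACCUG
GCAGAGGCUGCAGGAGUGCGCAUUCAAAAUAUCAACGGGCGACUCUACUUGAGGUAGUUCCUGAACAGGUGCAGGCGGGC
UGGGAGGCUGGUGACUGUUGGGUAAAGGAAACCUAGAUCGCUUCACUAAUCAAGAUAGCCGAAAGUUUCCCGAAACUUCC
GAACCCUGACGCUAACGAGCCCGAAUAGUAGUACGCGUGUACUCCACUGUCAGCACCCUUUACUCGCUUUAACGUCACGC
GACAACACCACGCUGCUGACGCAAACCAGAUCGGAAAUGGUGGAUUGCCUACAAAGUGAACGAGUCUUGGGUGGCACUUA
GUACGGUAGUCCGCGUAGACUCGCGGGCCAGACCGGGUGCCGCGAACAUAUCCGCAGGCCAUGACCUUUUAAGCUAUCCA
AUUAAGCUCUCCCAAUAGAGGUUGGGUGCUGAAAAUCAAAUGGCCGACCCCGUUCCAGAUCUGUUGAAAAUUUGGCUCGU
GGUAUGUCUGAGUCUCCCGGGACAGUAAACCACCAGAUCAAUUGUUUACGCGUACAUACCAUCUGUUGUAGUCGUCCCAU
AUUAUGAACGAAUCUUGAGGCGAUGGGCCUGUUAGGAGCCGGCGUAAAGGAGUUAGUAGAACGUUUUGCGUCCGGUGGGG
GACUUACUCUUGCCGAUUGACGACAGAAGACCUAGAGAAAGCAUUGAGCGCACCAGUAGCCCCCCUGGUUAAGGCACGCU
CCAGGACGAUUGCAGGUCACGUUUAGGCGGUAGCCCGAUCAGGAUUGUCAGAUCACGCGACCGAGCUAGGAUUAAGCUAG
AAUAGUUUUUCUGAGACUCUGCACGCCGUUUAACCUCUUCACUGGCCGCUCGCUUAUACGGUAGGCGCCUUAGAGCGCGU
CUUGCGGCUGAUUCCGAGAUGAAUGCUCAGUUCUUCAAUCAUCCCACGCUUCCAGCAUACAAUUAAAUCACGCCGACAUA
AGUCCCAGAGACGCCAUGCGCUGACUAUUGUUUUACUCCAUCCCGUUCGGUACUCAUUCUAGGACCGUCCACUUGGAGAC
GAUCUAUACAUUAGGUCGGUUAAUCCUCGCUUACGCGACCGCUGAUAUUCCGCAUUUGCCGAAUACCCGGAAUGACGAAA
CGUGAUUUUGCCAGCAAGCCCAGUGCUAGUCAAUACGGAGCACUUUUUAGGGAACGAUAAAUUCCGGCACGCGGGUGUUA
GGAUGAGCUUAGCUUAAUGCAAUGACUAGUUACAUAACCCGGAUGGACUGCUGGCUGGUUCUCCAUUUAACUGGGAUAAU
ACACAGAGCGCAUAAGUGGAUUCAAUUUAGUCCACUGUGCAUCAACGAGUUGAUGGAUUAUGUCUUGAGGCCACGUGCAA
CAACUGUAAAUAAUUUGACCGGGCGAUCUUAAUUAGGUUGUUACGUACCGUGCAGGGGGCCGCGUAUGCUGUGCCAGCCU
CCACGCGAGCGGGAUGGGAAUCAUGCGGGCACAGAAGGGGGUUUACAGUUAGGGUGGCAUCUUAAGUAACGCCCAGUCGU
UCAGACCUUCUGACUGCUAUAAAGACAGGGCGCGGUUGCAUCACCGUGAAAACUAUCCGGAUGCGUCCCAAGAGUAGAUA
CGCAAGUGCAAACUUUUUAAAGCGUCGGUUCCUACGUCCGUCCUUUCUAUAUGUAGUGUCUGUGGCGGAGUCAGAAAUCU
AUCAAACAUCACACGGGGACCACUAGCACAACACUAAGGAUUUGACGACCCACUAAGACCGGUACCGAUCGGUAACGUUC
GCGGCAUAGGGGGUUUGCUGCUCCCCCCUGAUAAACAGAGACCGACGUUCCGUUCUGGAGAUAGUGUACAGCGGUAGCGC
UCAGAUACUGUCGAGGGGCCUGACGUAGUAGUAAUCAGAACUCGGUUCUGGAUAUUGAGCUCGCAAUGGCCUAGGAAGGU
UAUAAGCGCCCGGUCAUCGCUUCCCUUCCUAGCUUAUUCGCUCACUUAUUAAUGCACCCGACCUCUAUGAAUUUUUGUUA
AAGUCGAGAACAGUAAGCUUGUGCGCUGUGCCAUUUCGAGGGCCCAUUCUCAACAGUUAAUUCCUACCACUUUUUUACGC
UCGAUUUUAGCGUUGUGAACCCGAGCUGGUCCCCGGGCCUGAUGCCGGAUAUGCUAGAGGAUUCCGCCCGGUUUAGCUGA
CCCGCACAUGUGGCGCAAAAAUGACGAUGUUCUUUCUCGCGAACUGGCACGGCUUUCCAUUACGAAGCAGGGCUCCAAGU
AAGUCCGGUAGCCGUCGUAGAAACCAAGGACUGCGUUGUAGACUGAGAACACGUAGGUACAUGGCUGUUUCCUAGUUUCA
AGUACGGCGAGGCCUAGUUGGAUUCCCGUGAAAAUCCCGAACGCCUGAGUGCUCUGAGUCGGUGUCGGUGAGUAGGCCAC
CGCUAGGCAACAGUGAUUGACAUCAUGGGCUGGUCUGCCUUGUAUGUAAUAAUCGUGUCAUGGCGCAGUAUGGAUAACUA
GCUGUGGGUGCAAAGCAUCUGGACAGCUGCUAUGCCGCAUGCACCACAAACAGGUUAUUAGAUCGUUAUACUCCAUAUAC
AUACCCGUCUCGACGAUACGAGCCGGCCCGACUAUCGCCGCGUGGGCACUUCACUUCCUAACUCAACACCCGUCGCCUAU
UCAGGGCUCUCAAACCGGUAGUCCUGGACAACAUCACAAGUCCGGGGGCCAACCUGGCAAAGCUAGCCCAGGUUAUCGUG
GAGAGUCACGGCACCUACCUUAUUCGUAAUGCCUUCGCGGAACGACAACAACCAGGAGGCGGGUUUCAAACCAGUGAGAC
AAACGGCGGACGCCCGGGUAUGUUCCCAAAGCCGGACGCUCAGUCUACAUUUGAUAACACCUAAACUGCGGUAGCCCUGG
CAGGGCGUUUUAAAUUCCGUCGGAGACUCGCUAGAC
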