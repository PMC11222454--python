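>rno-miR-496-3p synthetic fixture sequence
UAGUAUUACAUGGCCAAUCU
>hsa-miR-496-3p synthetic fixture sequence
UAGUAUGACAUGGCCAAUCU
>rno-miR-21-3p synthetic fixture sequence
CAACACCAGUCGAUGGGCUG
>hsa-miR-21-3p synthetic fixture sequence
CAACAGCAGUCGAUGGGCUG
>rno-miR-361-3p synthetic fixture sequence
UCCCCCAGGUGUGAUUCUGA
>hsa-miR-361-3p synthetic fixture sequence
UCACCCAGGUGUGAUUCUGA
>rno-miR-132-3p synthetic fixture sequence
UAACAGUCUACAGCCAUGGUCG
>hsa-miR-132-3p synthetic fixture sequence
CAACAGUCUACAGCCAUGGUCG
>rno-let-7c-5p synthetic fixture sequence
UGAGGUAGUAGGUUGUAUGGUU
>hsa-let-7c-5p synthetic fixture sequence
AGAGGUAGUAGGUUGUAUGGUU
>rno-miR-155-5p synthetic fixture sequence
UUAAUGCUAAUUGUGAUAGGGGU
>hsa-miR-155-5p synthetic fixture sequence
UUAAUGCUAAUCGUGAUAGGGGU
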