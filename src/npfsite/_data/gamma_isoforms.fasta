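>Ggamma1 GNGT1 human G protein gamma-T1 (transducin gamma), farnesylated
MPVINIEDLTEKDKLKMEVDQLKKEVTLERMLVSKCCEEFRDYVEERSGEDPLVKGIPED
KNPFKELKGGCVIS
>Ggamma2 GNG2 human G protein gamma-2, geranylgeranylated
MASNNTASIAQARKLVEQLKMEANIDRIKVSKAAADLMAYCEAHAKEDPLLTPVPASENP
FREKKFFCAIL
>Ggamma3 GNG3 human G protein gamma-3
MKGETPVNSTMSIGQARKMVEQLKIEASLCRIKVSKAAADLMTYCDAHACEDPLITPVPT
SENPFREKKFFCALL
>Ggamma4 GNG4 human G protein gamma-4
MKEGMSNNSTTSISQARKAVEQLKMEACMDRVKVSQAAADLLAYCEAHVREDPLIIPVPA
SENPFREKKFFCALL
>Ggamma5 GNG5 human G protein gamma-5
MSGSSSVAAMKKVVQQLRLEAGLNRVKVSQAAADLKQFCLQNAQHDPLLTGVSSSTNPFR
PQKVCSFL
>Ggamma7 GNG7 human G protein gamma-7
MSATNNIAQARKLVEQLRIEAGIERIKVSKAASDLMSYCEEHARSDPLLVGVPASENPFK
DKKPCIIL
>Ggamma8 GNG8 human G protein gamma-8
MSNNTASIAQARKTVEQLKLEVNIDRMKVSQAAAELLAFCEAHAKEDPLVTPVPASENPF
RDKKFFCALL
>Ggamma9 GNGT2 human G protein gamma-T2 (cone transducin gamma), farnesylated
MAQNLSEKDLLKMEVEQLRKEVKNTRIPISKAGKEIKEYVEAQAGNDPFLKGIPEDKNPF
KEKGSCVIS
>Ggamma10 GNG10 human G protein gamma-10
MSSGASASALQRLVEQLKLEAGVERIKVSQAAAELQQYCMQNACKDALLVGVPAGSNPFR
EPRSCALL
>Ggamma11 GNG11 human G protein gamma-11, farnesylated
MPALHIEDLPEKEKLKMEVEQLRKEVKLQRQQVSKCSEEIKNYIEERSGEDPLVKGIPED
KNPFKEKGGCLIS
>Ggamma12 GNG12 human G protein gamma-12
MSSKTASTNNIAQARRTVQQLRLEASIERIKVSKASADLMSYCEEHARNDPLLIGIPTSE
NPFKDKKTCIIL
>Ggamma13 GNG13 human G protein gamma-13
MEEWDVPQMKKEVESLKYQLAFQREMASKTIPELLKWIEDGIPKDPFLNPYSENPFVEKG
SCTIL
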