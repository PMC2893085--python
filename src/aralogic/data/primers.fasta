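>araB3
CATACTCGAGCCATTCAGAGAAGAAACCAA
>araB5
GATGCGGCCGCAGTGACGGCAATGTCTGAT
>araC3
GATGCGGCCGCCGTCAATTGTCTGATTCGT
>araC5
GATGCGGCCGCAGTGACGGCAATGTCTGAT
>araE3
GGGGATCCGGCGTTAAAGCAGATTCCGTAT
>araE5
CGCCTCGAGCCGTGGATGGCGGTTGGCTGG
>araF3
CCCCGGATCCCAGACCAATGGCTGCCAGGG
>araF5short
CCGCTCGAGCGGTTATTACACCATTTC
>sigARARS
ATGGATCCTAGTAGCATTTTTATCCATAAGATTAGCGATCCTACCTGAGGAGCCAATTCACG
>araCI1I2
ATGGATCCTAGTAGCATTTTTATCCATAAGATTAGCGATCCTACCTGAGGAGCCAATTGCACG
>araCI2I2
ATGGATCCTAGTAGCCGATTCTACCTGATCTATAGCCGATTCTACCTGAGGAGCCAATTGCACG
>araCDI1I2
ATGGATCCTAGNAGCNTTTTTATCNATATCTATAGCCGATTCTACCTGAGGAGCCAATTGCACG
>araCI1I1
ATGGATCCTAGTAGCATTTTTATCCATAAGATTAGCATTTTTATCCATAGGAGCCAATTGCACG
>araCDI2DI2
ATGGATCCTAGTNGCCGATTCTACNTGATCTATNGCCGATTCTACNTGAGGAGCCAATTGCACG
>sigCRP
GGATCCTAGAATNGTGNTCTNAATCACATNTGGAGCCAATTGCACG
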