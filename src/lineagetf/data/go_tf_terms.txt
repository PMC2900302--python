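GO:0000156
GO:0003700
GO:0003701
GO:0003702
GO:0003704
GO:0003705
GO:0003706
GO:0003709
GO:0003711
GO:0003712
GO:0003713
GO:0003714
GO:0003715
GO:0003716
GO:0003717
GO:0003718
GO:0008140
GO:0008148
GO:0008159
GO:0016251
GO:0016252
GO:0016455
GO:0016563
GO:0016564
GO:0016565
GO:0016566
GO:0016943
GO:0016944
GO:0016945
GO:0016986
GO:0016987
GO:0016988
GO:0016989
GO:0017163
GO:0030374
GO:0030375
GO:0030401
GO:0030528
GO:0042156
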