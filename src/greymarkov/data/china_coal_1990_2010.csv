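year,deaths
1990,7185
1991,6269
1992,5854
1993,5152
1994,6574
1995,6222
1996,6496
1997,6141
1998,6304
1999,6478
2000,5798
2001,5670
2002,6995
2003,6702
2004,6027
2005,5986
2006,4746
2007,3786
2008,2631
2009,2631
2010,2433
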