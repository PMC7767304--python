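plot,soil_type,contains_barley,n_images,n_beet_annotations,n_potato_annotations
1,Sandy,Yes,188,645,71
2,Sandy,No,188,678,76
3,Sandy,No,180,579,64
4,Sandy,Yes,176,365,75
5,Peaty,Yes,180,744,75
6,Peaty,No,184,718,72
7,Peaty,No,176,563,57
8,Peaty,Yes,184,543,87
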