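part,acquisition_date,contains_barley,lighting,resolution,n_images,n_beet_annotations,n_potato_annotations
a,20 May 2019,No,Controlled,2048 x 1536,280,1177,440
b,9 August 2019,Yes,Controlled,2048 x 1536,228,738,336
c,2017,No,Natural,640 x 480,250,0,0
d,Summer 2018,No,Natural,1280 x 1024,250,631,193
e,28 May 2018 and 1 June 2018,No,Controlled,2076 x 2076,250,794,161
f,28 May 2018 and 1 June 2018,Yes,Natural,2076 x 2076,250,734,195
g,28 May 2018,No,Controlled,1280 x 720,250,554,93
h,28 May 2018 and 1 June 2018,Yes,Natural,1280 x 720,250,484,121
i,4 May 2019,No,Natural,1280 x 720,250,1271,170
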