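id,name,node_class,laterality,mirror_id
1,Left forebrain,central_nervous,left,3
2,Forebrain central axis,central_nervous,midline,
3,Right forebrain,central_nervous,right,1
4,Left midbrain,central_nervous,left,6
5,Midbrain central axis,central_nervous,midline,
6,Right midbrain,central_nervous,right,4
7,Left hindbrain,central_nervous,left,9
8,Hindbrain central axis,central_nervous,midline,
9,Right hindbrain,central_nervous,right,7
10,Spinal cord central axis,central_nervous,midline,
11,Left spinal cord,central_nervous,left,12
12,Right spinal cord,central_nervous,right,11
13,Parietal left,skeletal,left,14
14,Parietal right,skeletal,right,13
15,Sphenoid,skeletal,midline,
16,Zygomatic left,skeletal,left,17
17,Zygomatic right,skeletal,right,16
18,Frontal,skeletal,midline,
19,Ethmoidal,skeletal,midline,
20,Nasal left,skeletal,left,21
21,Nasal right,skeletal,right,20
22,Maxilla left,skeletal,left,23
23,Maxilla right,skeletal,right,22
24,Lacrimal left,skeletal,left,25
25,Lacrimal right,skeletal,right,24
26,Palatine left,skeletal,left,27
27,Palatine right,skeletal,right,26
28,Vomer,skeletal,midline,
29,Malleus left,skeletal,left,30
30,Malleus right,skeletal,right,29
31,Incus left,skeletal,left,32
32,Incus right,skeletal,right,31
33,Stapes left,skeletal,left,34
34,Stapes right,skeletal,right,33
35,Occipital,skeletal,midline,
36,Temporal left,skeletal,left,38
37,Mandible,skeletal,midline,
38,Temporal right,skeletal,right,36
39,Hyoid bone,skeletal,midline,
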