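year,location,M1,M2,M3,M4,M5,M6,M7,M8,M9,best,nonconverged,nonpd
2009,G-L1,101.7,84.3,45.5,47.2,20.4,6.9,45.6,0,1.7,M8,,
2009,G-L2,83.1,67.5,50.9,38.5,31.4,20.7,40.7,0.5,0,M9,,
2009,G-L3,45.7,30.4,41.5,31.1,40.1,26.9,31.2,1.0,0,M9,,
2009,G-L4,125.0,19.1,125.1,114.9,90.3,19.6,115.5,65.0,0,M9,,
2009,G-L5,29.1,8.0,18.1,24.5,15.3,1.2,,12.3,0,M9,M7,
2009,G-L6,51.6,47.6,37.7,29.5,41.7,35.4,29.4,0,1.2,M8,,
2009,G-L7,81.5,56.1,55.3,62.8,36.5,11.0,55.5,5.1,0,M9,,
2009,P-L1,126.4,115.6,121.6,116.3,109.5,108.8,116.2,0,1.9,M8,,
2009,P-L2,62.3,45.4,62.4,54.6,57.3,47.2,54.9,1.5,0,M9,,
2009,P-L3,120.9,65.9,116.1,105.5,99.7,49.6,105.5,17.3,0,M9,,
2009,P-L4,145.9,98.6,132.8,126.4,126.4,80.1,126.4,0.4,0,M9,,
2010,G-L1,35.5,4.9,35.6,31.5,12.3,0,32.0,12.3,1.8,M6,,
2010,G-L2,25.0,7.2,27.0,21.7,29.7,11.9,19.7,0,-3.2,M8,,M9
2010,G-L4,141.4,74.2,128.7,117.1,130.2,57.4,118.4,5.0,0,M9,,
2010,G-L5,21.6,0,23.4,22.9,21.9,3.3,22.9,22.1,2.8,M2,,
2010,G-L6,80.9,60.0,72.8,59.8,55.4,41.5,61.1,0,0.6,M8,,
2010,G-L7,69.5,22.3,56.2,47.8,37.2,23.6,48.1,2.6,0,M9,,
2010,G-L8,40.8,24.7,32.1,22.6,27.7,19.6,23.1,0,1.4,M8,,
2010,P-L1,38.8,5.7,38.8,38.8,39.4,9.4,40.8,39.1,0,M9,,
2010,P-L2,40.0,0.7,41.6,36.1,39.8,4.1,36.9,4.3,0,M9,,
2010,P-L3,66.4,0,68.4,67.2,69.5,3.7,70.4,71.5,5.7,M2,,
2010,P-L4,95.0,80.4,90.5,79.1,87.0,66.7,79.4,0,3.2,M8,,
2012,G-L4,35.3,0,35.3,36.2,26.0,0.6,35.3,24.2,,M2,M9,
2012,G-L5,66.3,2.6,67.0,66.3,42.1,5.9,,21.5,0,M9,M7,
2012,G-L6,148.4,131.4,93.8,93.7,18.7,18.7,89.9,0,0,M8;M9,,
2012,G-L7,38.3,4.5,40.3,38.3,36.3,0,42.3,,1.9,M6,M8,
2012,G-L8,45.3,39.8,37.7,33.5,35.6,37.3,33.9,1.9,0,M9,,
2012,G-L9,402.3,321.5,200.9,181.7,81.9,81.9,191.6,0,0,M8;M9,,
2012,G-L10,39.7,0,41.5,41.4,22.1,3.5,43.5,6.7,1.1,M2,,
2012,G-L11,18.0,0,19.7,18.0,8.4,1.2,21.6,3.7,,M2,M9,
2012,P-L1,189.5,168.8,158.9,148.9,146.3,137.8,149.1,0,1.7,M8,,
2012,P-L2,127.4,49.3,129.1,122.6,129.7,49.9,123.9,5.9,0,M9,,
2012,P-L3,107.8,55.3,103.1,95.0,101.0,49.3,96.1,7.9,0,M9,,
2012,P-L4,226.3,0.2,226.3,222.1,226.3,0,226.3,226.3,2.0,M6,,
2012,P-L5,13.2,0,13.2,13.2,11.9,1.5,13.2,13.9,3.5,M2,,
2012,P-L6,79.0,54.8,70.4,66.9,65.8,37.9,67.0,0,1.7,M8,,
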